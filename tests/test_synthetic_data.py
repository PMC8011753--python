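"""Generator properties: determinism, marginal structure, ground truth."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from pacseq.power_sim import LossProfile
from pacseq.synthetic_data import (
    SimConfig,
    make_barcode_distribution,
    make_control_matrix,
    make_guide_counts,
    make_guide_reads,
    make_guide_reference,
    make_mixture_counts,
    make_perturbed_population,
    make_screen,
)
from pacseq.cell_qc import knee_filter


class TestControlMatrix:
    def test_fixed_seed_deterministic(self):
        cfg = SimConfig(seed=8, n_cells=100, n_genes=50)
        a, mu_a = make_control_matrix(cfg)
        b, mu_b = make_control_matrix(cfg)
        assert np.array_equal(a.matrix.toarray(), b.matrix.toarray())
        assert a.barcodes == b.barcodes
        assert np.array_equal(mu_a, mu_b)

    def test_empirical_means_track_truth(self, control_matrix):
        cm, mu = control_matrix
        emp = np.asarray(cm.matrix.mean(axis=0)).ravel()
        assert spearmanr(emp, mu).statistic >= 0.95

    def test_poisson_limit_at_zero_dispersion(self):
        cfg = SimConfig(seed=8, n_cells=3000, n_genes=20, dispersion=0.0,
                        depth_sigma=0.0, mean_range=(5.0, 20.0), n_mito=0)
        cm, mu = make_control_matrix(cfg)
        dense = cm.matrix.toarray()
        ratio = dense.var(axis=0) / dense.mean(axis=0)
        assert np.all(np.abs(ratio - 1.0) < 0.25)

    def test_mito_genes_flagged_and_fraction(self, control_matrix):
        cm, _ = control_matrix
        mito = [f for f in cm.features if f.startswith("mt-")]
        assert len(mito) == 10
        frac = cm.matrix[:, [cm.features.index(f) for f in mito]].sum() / cm.matrix.sum()
        assert frac == pytest.approx(0.05, abs=0.01)

    def test_mean_range_spans_three_decades(self, control_matrix):
        _, mu = control_matrix
        assert mu.max() / mu.min() >= 1000


class TestGuideCounts:
    def test_bimodal_count_fractions(self):
        cfg = SimConfig(seed=9, n_cells=800)
        gc, truth = make_guide_counts(cfg)
        dense = gc.matrix.toarray().astype(float)
        totals = dense.sum(axis=1)
        frac = dense[:, 0] / np.maximum(totals, 1)
        own = truth.true_guide == "sg01"
        assert np.median(frac[own.to_numpy()]) == pytest.approx(0.95, abs=0.05)
        assert np.median(frac[~own.to_numpy()]) < 0.02

    def test_deterministic_and_totals_consistent(self):
        cfg = SimConfig(seed=9, n_cells=100)
        a, _ = make_guide_counts(cfg)
        b, _ = make_guide_counts(cfg)
        assert np.array_equal(a.matrix.toarray(), b.matrix.toarray())
        assert np.array_equal(a.row_totals(), a.matrix.toarray().sum(axis=1))

    def test_noise_free_limit(self):
        cfg = SimConfig(seed=9, n_cells=60, p_noise=0.0, p_signal=1.0)
        gc, truth = make_guide_counts(cfg)
        dense = gc.matrix.toarray()
        for i, gid in enumerate(truth.true_guide):
            j = gc.features.index(gid)
            assert dense[i].sum() == dense[i, j]

    def test_unidentifiable_truth_rejected(self):
        with pytest.raises(ValueError):
            make_guide_counts(SimConfig(seed=1, p_noise=0.5, p_signal=0.4))
        with pytest.raises(ValueError):
            make_mixture_counts(10, p_noise=0.5, p_signal=0.4)


class TestPerturbedPopulation:
    def test_no_loss_identity(self, rng):
        cfg = SimConfig(seed=10, n_cells=50, n_genes=30)
        cm, _ = make_control_matrix(cfg)
        out, truth = make_perturbed_population(cm, cm.features[5], LossProfile(0, 0), rng)
        assert np.array_equal(out.matrix.toarray(), cm.matrix.toarray())
        assert (truth.loss_state == "none").all()

    def test_full_loss_zeroes_target_only(self, rng):
        cfg = SimConfig(seed=10, n_cells=50, n_genes=30)
        cm, _ = make_control_matrix(cfg)
        target = cm.features[25]
        out, truth = make_perturbed_population(cm, target, LossProfile(0, 1.0), rng)
        j = cm.features.index(target)
        assert out.matrix[:, j].sum() == 0
        others = [c for c in range(30) if c != j]
        assert np.array_equal(
            out.matrix.toarray()[:, others], cm.matrix.toarray()[:, others]
        )
        assert (truth.loss_state == "bi").all()

    def test_state_fractions_within_binomial_ci(self, rng):
        cfg = SimConfig(seed=10, n_cells=2000, n_genes=10)
        cm, _ = make_control_matrix(cfg)
        loss = LossProfile(0.25, 0.05)
        _, truth = make_perturbed_population(cm, cm.features[0], loss, rng)
        counts = truth.loss_state.value_counts()
        for state, f in (("mono", 0.25), ("bi", 0.05)):
            se = np.sqrt(f * (1 - f) / 2000)
            assert counts.get(state, 0) / 2000 == pytest.approx(f, abs=3 * se)


class TestBarcodeDistribution:
    def test_knee_recovers_real_cells(self, default_cfg):
        dist = make_barcode_distribution(default_cfg)
        kept = set(knee_filter(dist["total"], expected_cells=default_cfg.n_cells))
        real = set(dist.index[dist["is_real"]])
        assert len(kept & real) / len(real) >= 0.99
        assert len(kept - real) / max(len(kept), 1) <= 0.01

    def test_zero_ambient_all_retained(self):
        cfg = SimConfig(seed=12, n_cells=300, n_ambient=0)
        dist = make_barcode_distribution(cfg)
        kept = knee_filter(dist["total"], expected_cells=300)
        assert len(kept) == 300

    def test_seed_determinism(self):
        cfg = SimConfig(seed=13, n_cells=100, n_ambient=100)
        assert make_barcode_distribution(cfg).equals(make_barcode_distribution(cfg))


class TestGuideReads:
    def test_empty_matrix_no_reads(self):
        cfg = SimConfig(seed=14, n_cells=5, n_guides=3, grna_total_mean=4)
        refs = make_guide_reference(cfg)
        gc, _ = make_guide_counts(cfg)
        empty = gc.subset_cells(np.zeros(5, dtype=bool))
        assert make_guide_reads(cfg, empty, refs) == []

    def test_sequencing_errors_mostly_recoverable(self):
        from pacseq.grna_quant import GuideAligner, count_umis

        cfg = SimConfig(seed=14, n_cells=20, n_guides=4, grna_total_mean=5,
                        grna_total_dispersion=0.0, error_rate=0.01)
        refs = make_guide_reference(cfg)
        gc, _ = make_guide_counts(cfg)
        reads = make_guide_reads(cfg, gc, refs)
        cm = count_umis(GuideAligner(refs).align_stream(reads), [r.guide_id for r in refs])
        assert cm.matrix.sum() >= 0.99 * gc.matrix.sum()


def test_make_screen_consistency():
    cfg = SimConfig(seed=15, n_cells=10, n_genes=60, n_guides=4)
    screen = make_screen(cfg, cells_per_guide=40, target_gene="Gene00040")
    expr, gc, truth = screen["expression"], screen["guide_counts"], screen["truth"]
    assert expr.shape == (160, 60)
    assert gc.shape == (160, 4)
    assert expr.barcodes == gc.barcodes
    # loss only in the perturbed population
    perturbed = truth.true_guide == "sg02"
    assert (truth.loss_state[~perturbed.to_numpy()] == "none").all()
    assert (truth.loss_state[perturbed.to_numpy()] != "none").any()
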