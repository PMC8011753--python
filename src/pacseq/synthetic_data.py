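"""Synthetic droplet scRNA-seq and gRNA-library generators with ground truth.

Every stage of the pipeline can be exercised without external data:

* control transcriptomes — negative-binomial UMI counts (gamma-Poisson)
  with log-normal per-cell depth factors, gene means log-spaced over more
  than three orders of magnitude so every expression bucket populates, and
  a small flagged set of mitochondrial genes;
* gRNA UMI count matrices with known per-cell guide labels, where the true
  guide's counts are Binomial(n_i, p_signal) of the cell's total and the
  remainder is spread over the other guides as noise, reproducing the
  bimodal count-fraction structure the mixture model expects;
* perturbed populations with known per-cell monoallelic (0.5-thinned) or
  biallelic (zeroed) loss states for a target gene;
* barcode total distributions with an ambient tail forming a knee;
* paired FASTQ reads for the gRNA-enriched library.

Every generator is a pure function of its configuration (the seed is part
of the configuration); distinct generators use distinct derived streams so
they are independent of each other.

These fixtures emulate the statistical structure of droplet data (over-
dispersion, depth variation, ambient barcodes), not any particular real
dataset: real data add ambient guide contamination, barcode collisions and
doublets, which are deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from .io_formats import CountMatrix, GuideReference, TaggedRead, write_tagged_fastq
from .power_sim import LossProfile

# canonical SpCas9 scaffold with a 25-adenine tract appended, so the guide
# transcript is capturable by oligo(dT) priming
SCAFFOLD_25A = (
    "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGTGGCACCGAGTCGGTGC"
    + "A" * 25
)

_BASES = np.array(list("ACGT"))

# stream labels keeping the generators independent under one seed
_STREAM_CONTROL = 1
_STREAM_GUIDES = 2
_STREAM_PERTURB = 3
_STREAM_BARCODES = 4
_STREAM_READS = 5
_STREAM_PANEL = 6


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for all synthetic fixtures (seed mandatory)."""

    seed: int
    # transcriptome
    n_cells: int = 2000
    n_genes: int = 1000
    mean_range: tuple[float, float] = (0.02, 30.0)  # UMIs/cell, log-spaced
    dispersion: float = 0.1  # NB: var = m (1 + dispersion * m); 0 -> Poisson
    depth_sigma: float = 0.3  # log-normal spread of per-cell depth factors
    n_mito: int = 10
    mito_frac: float = 0.05
    # guide library
    n_guides: int = 10
    grna_total_mean: float = 150.0  # per-cell total gRNA UMIs
    grna_total_dispersion: float = 0.05
    p_noise: float = 0.005
    p_signal: float = 0.95
    # perturbation truth
    loss: LossProfile = field(default_factory=lambda: LossProfile(0.25, 0.05))
    # ambient barcodes
    n_ambient: int = 5000
    ambient_scale: float = 30.0  # mean ambient total; <1% of a real cell
    # read generation
    barcode_len: int = 16
    umi_len: int = 10
    read_len: int = 60
    error_rate: float = 0.0
    reads_per_umi: int = 1

    def __post_init__(self) -> None:
        for name in ("p_noise", "p_signal", "mito_frac", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_cells < 1 or self.n_genes < 1:
            raise ValueError("n_cells and n_genes must be positive")


@dataclass
class GroundTruth:
    """Generating truth for a simulated screen."""

    true_guide: pd.Series | None = None  # per-cell guide label
    loss_state: pd.Series | None = None  # per-cell none/mono/bi for the target
    guide_params: pd.DataFrame | None = None  # per-guide (p_noise, p_signal, pi)


def _random_dna(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """Distinct random DNA strings."""
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        chunk = ["".join(_BASES[rng.integers(0, 4, size=length)]) for _ in range(n - len(out))]
        for s in chunk:
            if s not in seen:
                seen.add(s)
                out.append(s)
    return out


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draws with var = m (1 + dispersion * m)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, dispersion * mean)
    return rng.poisson(lam)


def true_gene_means(cfg: SimConfig) -> tuple[np.ndarray, list[str]]:
    """Per-gene true mean expression (UMIs per unit depth) and gene names.

    Means are log-spaced over ``mean_range``; the last ``n_mito`` genes are
    mitochondrial (``mt-`` prefix) with means scaled so their expected
    share of counts is ``mito_frac``.
    """
    n_body = cfg.n_genes - cfg.n_mito
    mu = np.geomspace(cfg.mean_range[0], cfg.mean_range[1], n_body)
    names = [f"Gene{j:05d}" for j in range(n_body)]
    if cfg.n_mito:
        mito_total = cfg.mito_frac / (1.0 - cfg.mito_frac) * mu.sum()
        mito_mu = np.full(cfg.n_mito, mito_total / cfg.n_mito)
        mu = np.concatenate([mu, mito_mu])
        names += [f"mt-{j + 1}" for j in range(cfg.n_mito)]
    return mu, names


def make_control_matrix(cfg: SimConfig) -> tuple[CountMatrix, np.ndarray]:
    """Simulate an unperturbed control population; returns (counts, true means)."""
    rng = np.random.default_rng([cfg.seed, _STREAM_CONTROL])
    mu, names = true_gene_means(cfg)
    depth = rng.lognormal(0.0, cfg.depth_sigma, size=cfg.n_cells)
    mean = depth[:, None] * mu[None, :]
    counts = _nb_counts(rng, mean, cfg.dispersion)
    barcodes = _random_dna(rng, cfg.n_cells, cfg.barcode_len)
    return CountMatrix(sparse.csr_matrix(counts), barcodes, names), mu


def make_guide_reference(cfg: SimConfig) -> list[GuideReference]:
    """A guide panel with random spacers on the shared 25A scaffold."""
    rng = np.random.default_rng([cfg.seed, _STREAM_PANEL])
    spacers = _random_dna(rng, cfg.n_guides, 20)
    return [
        GuideReference(f"sg{i + 1:02d}", sp, sp + SCAFFOLD_25A)
        for i, sp in enumerate(spacers)
    ]


def make_guide_counts(
    cfg: SimConfig,
    truth_labels: np.ndarray | None = None,
    barcodes: list[str] | None = None,
) -> tuple[CountMatrix, GroundTruth]:
    """Simulate the cells x guides UMI count matrix with known labels.

    Each cell's total gRNA UMI count n_i is negative-binomial; the true
    guide receives Binomial(n_i, p_signal) of it and the remainder is
    spread multinomially over the other guides, so each guide's marginal
    counts follow the signal+noise two-component structure.
    """
    if cfg.p_signal <= cfg.p_noise:
        raise ValueError("p_signal must exceed p_noise (unidentifiable truth)")
    rng = np.random.default_rng([cfg.seed, _STREAM_GUIDES])
    if truth_labels is None:
        truth_labels = rng.integers(0, cfg.n_guides, size=cfg.n_cells)
    truth_labels = np.asarray(truth_labels)
    n_cells = len(truth_labels)
    if barcodes is None:
        barcodes = _random_dna(rng, n_cells, cfg.barcode_len)
    totals = _nb_counts(
        rng, np.full(n_cells, cfg.grna_total_mean), cfg.grna_total_dispersion
    )
    counts = np.zeros((n_cells, cfg.n_guides), dtype=np.int64)
    for i in range(n_cells):
        g = truth_labels[i]
        k_true = rng.binomial(totals[i], cfg.p_signal)
        counts[i, g] = k_true
        leftover = totals[i] - k_true
        if leftover and cfg.n_guides > 1:
            others = np.ones(cfg.n_guides) * cfg.p_noise
            others[g] = 0.0
            if others.sum() > 0:
                counts[i] += rng.multinomial(leftover, others / others.sum())
            else:
                counts[i, g] += leftover
    guide_ids = [f"sg{i + 1:02d}" for i in range(cfg.n_guides)]
    cm = CountMatrix(sparse.csr_matrix(counts), list(barcodes), guide_ids)
    truth = GroundTruth(
        true_guide=pd.Series(
            [guide_ids[g] for g in truth_labels], index=barcodes, name="true_guide"
        ),
        guide_params=pd.DataFrame(
            {
                "guide_id": guide_ids,
                "p_noise": cfg.p_noise,
                "p_signal": cfg.p_signal,
                "pi_signal": [
                    float(np.mean(truth_labels == g)) for g in range(cfg.n_guides)
                ],
            }
        ),
    )
    return cm, truth


def make_mixture_counts(
    n_cells: int,
    *,
    p_noise: float = 0.005,
    p_signal: float = 0.95,
    pi_signal: float = 0.3,
    total_mean: float = 150.0,
    total_dispersion: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (k, n, z) directly from the two-component binomial mixture.

    The generating process the assignment model assumes: per-cell totals
    n_i are negative-binomial, z_i ~ Bernoulli(pi_signal), and
    k_i ~ Binomial(n_i, p_signal if z_i else p_noise).  Used to study
    parameter recovery of the EM fit against known truth.
    """
    if p_signal <= p_noise:
        raise ValueError("p_signal must exceed p_noise (unidentifiable truth)")
    rng = np.random.default_rng([seed, _STREAM_GUIDES, 1])
    n = np.maximum(_nb_counts(rng, np.full(n_cells, total_mean), total_dispersion), 1)
    z = rng.random(n_cells) < pi_signal
    k = rng.binomial(n, np.where(z, p_signal, p_noise))
    return k, n, z


def make_perturbed_population(
    control: CountMatrix,
    target_gene: str,
    loss: LossProfile,
    rng: np.random.Generator,
) -> tuple[CountMatrix, GroundTruth]:
    """Inject mono/biallelic loss of one gene into a copy of a count matrix.

    Per-cell loss states are sampled from (f_mono, f_full); monoallelic
    cells have the target gene's counts binomially thinned at 0.5,
    biallelic cells are zeroed, every other gene is untouched.
    """
    if target_gene not in control.features:
        raise ValueError(f"target gene {target_gene!r} not in the matrix")
    j = control.features.index(target_gene)
    counts = control.matrix.tolil(copy=True)
    col = np.asarray(control.matrix[:, j].todense()).ravel()
    u = rng.random(control.shape[0])
    full = u < loss.f_full
    mono = (~full) & (u < loss.f_full + loss.f_mono)
    new_col = col.copy()
    new_col[mono] = rng.binomial(col[mono].astype(np.int64), 0.5)
    new_col[full] = 0
    counts[:, j] = new_col[:, None]
    states = np.where(full, "bi", np.where(mono, "mono", "none"))
    truth = GroundTruth(
        loss_state=pd.Series(states, index=control.barcodes, name="loss_state")
    )
    return (
        CountMatrix(sparse.csr_matrix(counts), list(control.barcodes), list(control.features)),
        truth,
    )


def make_screen(
    cfg: SimConfig,
    cells_per_guide: int,
    target_gene: str,
    perturbed_guide: int = 1,
) -> dict:
    """Build a complete pooled screen: expression + guide counts + truth.

    ``n_guides`` populations of ``cells_per_guide`` cells each are pooled;
    the population carrying guide ``perturbed_guide`` has the configured
    loss profile injected into ``target_gene``, every other population is
    an unperturbed draw from the control model.  Returns a dict with keys
    ``expression`` (CountMatrix), ``guide_counts`` (CountMatrix),
    ``references``, ``truth`` (GroundTruth) and ``target_gene``.
    """
    n_cells = cfg.n_guides * cells_per_guide
    cfg_pool = replace(cfg, n_cells=n_cells)
    control, _mu = make_control_matrix(cfg_pool)
    labels = np.repeat(np.arange(cfg.n_guides), cells_per_guide)
    gcounts, truth = make_guide_counts(cfg_pool, labels, barcodes=list(control.barcodes))

    rng = np.random.default_rng([cfg.seed, _STREAM_PERTURB])
    j = control.features.index(target_gene)
    counts = control.matrix.tolil(copy=True)
    col = np.asarray(control.matrix[:, j].todense()).ravel()
    in_pop = labels == perturbed_guide
    u = np.where(in_pop, rng.random(n_cells), 1.0)  # only the targeted population
    full = u < cfg.loss.f_full
    mono = (~full) & (u < cfg.loss.f_full + cfg.loss.f_mono)
    new_col = col.copy()
    new_col[mono] = rng.binomial(col[mono].astype(np.int64), 0.5)
    new_col[full] = 0
    counts[:, j] = new_col[:, None]
    states = np.where(full, "bi", np.where(mono, "mono", "none"))
    truth.loss_state = pd.Series(states, index=control.barcodes, name="loss_state")
    expression = CountMatrix(
        sparse.csr_matrix(counts), list(control.barcodes), list(control.features)
    )
    return {
        "expression": expression,
        "guide_counts": gcounts,
        "references": make_guide_reference(cfg),
        "truth": truth,
        "target_gene": target_gene,
    }


def make_barcode_distribution(cfg: SimConfig) -> pd.DataFrame:
    """Per-barcode total UMI counts with an ambient tail forming a knee.

    Real cells draw totals around the configured depth (~4k UMIs); ambient
    barcodes draw around ``ambient_scale`` (default <1% of a real cell).
    Returns a frame with columns ``total`` and ``is_real``.
    """
    rng = np.random.default_rng([cfg.seed, _STREAM_BARCODES])
    mu, _ = true_gene_means(cfg)
    real_depth = mu.sum()
    real = rng.lognormal(np.log(real_depth), cfg.depth_sigma, size=cfg.n_cells)
    ambient = rng.lognormal(np.log(cfg.ambient_scale), 0.6, size=cfg.n_ambient)
    totals = np.concatenate([real, ambient]).round().astype(np.int64)
    barcodes = _random_dna(rng, cfg.n_cells + cfg.n_ambient, cfg.barcode_len)
    return pd.DataFrame(
        {
            "total": totals,
            "is_real": np.concatenate(
                [np.ones(cfg.n_cells, bool), np.zeros(cfg.n_ambient, bool)]
            ),
        },
        index=pd.Index(barcodes, name="cell_barcode"),
    )


def _mutate(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.flatnonzero(rng.random(len(arr)) < error_rate)
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def make_guide_reads(
    cfg: SimConfig,
    guide_counts: CountMatrix,
    references: list[GuideReference],
) -> list[TaggedRead]:
    """Emit read pairs realising a guide count matrix.

    For every (cell, UMI, guide) molecule, ``reads_per_umi`` read pairs are
    produced: read 1 is barcode + UMI, read 2 is a ``read_len`` prefix of
    the guide's full sequence with per-base substitution errors at
    ``error_rate``.  UMIs are distinct within each cell, so at error rate 0
    quantification reproduces the matrix exactly.
    """
    ref_by_id = {r.guide_id: r for r in references}
    rng = np.random.default_rng([cfg.seed, _STREAM_READS])
    reads: list[TaggedRead] = []
    dense = np.asarray(guide_counts.matrix.todense())
    rid = 0
    for i, barcode in enumerate(guide_counts.barcodes):
        n_mol = int(dense[i].sum())
        if n_mol == 0:
            continue
        umis = _random_dna(rng, n_mol, cfg.umi_len)
        m = 0
        for j, gid in enumerate(guide_counts.features):
            for _ in range(int(dense[i, j])):
                template = ref_by_id[gid].full_sequence[: cfg.read_len]
                for _rep in range(max(1, cfg.reads_per_umi)):
                    reads.append(
                        TaggedRead(
                            cell_barcode=barcode,
                            umi=umis[m],
                            sequence=_mutate(template, rng, cfg.error_rate),
                            read_id=f"sim{rid}",
                        )
                    )
                    rid += 1
                m += 1
    return reads


def make_guide_read_files(
    cfg: SimConfig,
    guide_counts: CountMatrix,
    references: list[GuideReference],
    r1_path: Path | str,
    r2_path: Path | str,
) -> int:
    """Write the simulated read pairs to paired FASTQ files."""
    return write_tagged_fastq(
        make_guide_reads(cfg, guide_counts, references), r1_path, r2_path
    )
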