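"""Map gRNA-enriched reads to a known guide panel and collapse to UMI counts.

Reads are aligned locally (Smith-Waterman with affine gaps) against each
guide's full sequence (spacer + invariant scaffold).  Because all guides
share the scaffold, a hit is only accepted when the alignment covers enough
of the variable spacer region to be informative; reads aligning equally
well to two or more guides are discarded as ambiguous.  Accepted hits are
collapsed to one molecule per unique (cell barcode, UMI, guide) triple.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from scipy import sparse

from .io_formats import CountMatrix, GuideReference, TaggedRead


@dataclass(frozen=True)
class AlignParams:
    """Scoring and acceptance parameters for the local aligner.

    A hit requires local alignment score >= ``min_score`` and at least
    ``min_spacer_overlap`` aligned reference bases inside the spacer
    (capped at the spacer length for short spacers).
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0
    min_score: float = 15.0
    min_spacer_overlap: int = 15


@dataclass(frozen=True)
class GuideHit:
    read_id: str | None
    guide_id: str | None
    score: float
    is_ambiguous: bool = False


class GuideAligner:
    """Local aligner bound to a guide panel; reusable across many reads."""

    def __init__(self, references: Sequence[GuideReference], params: AlignParams | None = None):
        if not references:
            raise ValueError("references must be non-empty")
        self.references = list(references)
        self.params = params or AlignParams()
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = self.params.match
        aligner.mismatch_score = self.params.mismatch
        aligner.open_gap_score = self.params.gap_open
        aligner.extend_gap_score = self.params.gap_extend
        self._aligner = aligner

    def _spacer_overlap(self, alignment, spacer_len: int) -> int:
        blocks = alignment.aligned[0]  # aligned blocks on the reference
        overlap = 0
        for start, end in blocks:
            overlap += max(0, min(int(end), spacer_len) - int(start))
        return overlap

    def align(self, sequence: str, read_id: str | None = None) -> GuideHit:
        """Best accepted guide for one read, or a no-hit / ambiguous record."""
        if not sequence or set(sequence) <= {"N"}:
            return GuideHit(read_id, None, 0.0)
        best_score = -np.inf
        best_guides: list[str] = []
        for ref in self.references:
            try:
                alignments = self._aligner.align(ref.full_sequence, sequence)
                alignment = alignments[0]
            except (IndexError, ValueError):
                continue
            score = float(alignment.score)
            if score < self.params.min_score:
                continue
            required = min(self.params.min_spacer_overlap, len(ref.spacer))
            if self._spacer_overlap(alignment, len(ref.spacer)) < required:
                continue
            if score > best_score:
                best_score = score
                best_guides = [ref.guide_id]
            elif score == best_score:
                best_guides.append(ref.guide_id)
        if not best_guides:
            return GuideHit(read_id, None, 0.0)
        if len(best_guides) > 1:
            return GuideHit(read_id, None, best_score, is_ambiguous=True)
        return GuideHit(read_id, best_guides[0], best_score)

    def align_stream(self, reads: Iterable[TaggedRead]) -> Iterator[tuple[TaggedRead, GuideHit]]:
        for read in reads:
            yield read, self.align(read.sequence, read.read_id)


def align_read(
    sequence: str,
    references: Sequence[GuideReference],
    params: AlignParams | None = None,
) -> GuideHit:
    """One-shot convenience wrapper around :class:`GuideAligner`."""
    return GuideAligner(references, params).align(sequence)


def count_umis(
    tagged_hits: Iterable[tuple[TaggedRead, GuideHit]],
    guide_ids: Sequence[str],
    valid_barcodes: set[str] | None = None,
) -> CountMatrix:
    """Collapse accepted hits to UMI-unique cells x guides counts.

    One count per distinct (barcode, UMI, guide) triple; reads with no hit
    or an ambiguous hit are discarded.  If the same (barcode, UMI) maps to
    two guides in different reads, both triples are kept (no arbitration);
    the downstream mixture model absorbs such noise.  Barcode order in the
    output is lexicographic.
    """
    triples: set[tuple[str, str, str]] = set()
    for read, hit in tagged_hits:
        if hit.guide_id is None:
            continue
        if valid_barcodes is not None and read.cell_barcode not in valid_barcodes:
            continue
        triples.add((read.cell_barcode, read.umi, hit.guide_id))
    barcodes = sorted({bc for bc, _, _ in triples})
    bc_pos = {b: i for i, b in enumerate(barcodes)}
    g_pos = {g: i for i, g in enumerate(guide_ids)}
    rows, cols = [], []
    for bc, _umi, gid in triples:
        rows.append(bc_pos[bc])
        cols.append(g_pos[gid])
    mat = sparse.csr_matrix(
        (np.ones(len(rows), dtype=np.int64), (rows, cols)),
        shape=(len(barcodes), len(guide_ids)),
    )
    return CountMatrix(mat, barcodes, list(guide_ids))


def mapping_summary(
    tagged_hits: Iterable[tuple[TaggedRead, GuideHit]],
    guide_ids: Sequence[str],
) -> pd.DataFrame:
    """Per-guide read-level mapping summary (reads, plus no-hit/ambiguous rows)."""
    counts: dict[str, int] = {g: 0 for g in guide_ids}
    n_nohit = n_ambig = 0
    for _read, hit in tagged_hits:
        if hit.guide_id is not None:
            counts[hit.guide_id] += 1
        elif hit.is_ambiguous:
            n_ambig += 1
        else:
            n_nohit += 1
    rows = [{"guide_id": g, "n_reads": counts[g]} for g in guide_ids]
    rows.append({"guide_id": "__ambiguous__", "n_reads": n_ambig})
    rows.append({"guide_id": "__unmapped__", "n_reads": n_nohit})
    return pd.DataFrame(rows)
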