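"""Readers and writers for the standard formats the pipeline touches.

Count matrices follow the 10x droplet convention on disk (MatrixMarket
coordinate file with features as rows and barcodes as columns, 1-based
coordinates, integer field) and are held cells x features in memory.
FASTQ pairs carry the cell barcode and UMI on read 1 and the gRNA cDNA
sequence on read 2.  All text formats are accepted gzip-compressed
transparently (``.gz`` suffix).
"""

from __future__ import annotations

import gzip
import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from scipy import io as scipy_io
from scipy import sparse

logger = logging.getLogger(__name__)

_DNA_RE = re.compile(r"^[ACGTN]+$")


@dataclass(frozen=True)
class GuideReference:
    """A known gRNA: unique id, variable spacer, and spacer + invariant scaffold.

    The spacer is the ~20 nt targeting portion; ``full_sequence`` is the
    cDNA the enriched library actually reads (spacer followed by the
    invariant hairpin/scaffold, possibly with the poly-A tract).
    """

    guide_id: str
    spacer: str
    full_sequence: str

    def __post_init__(self) -> None:
        if not self.guide_id:
            raise ValueError("guide_id must be non-empty")
        for label, seq in (("spacer", self.spacer), ("full_sequence", self.full_sequence)):
            if not _DNA_RE.match(seq):
                raise ValueError(
                    f"guide {self.guide_id!r}: {label} contains non-ACGTN characters: {seq!r}"
                )
        if not self.full_sequence.startswith(self.spacer):
            raise ValueError(
                f"guide {self.guide_id!r}: spacer is not a prefix of full_sequence"
            )


@dataclass(frozen=True)
class TaggedRead:
    """One read pair reduced to (cell barcode, UMI, cDNA sequence)."""

    cell_barcode: str
    umi: str
    sequence: str
    quality: str | None = None
    read_id: str | None = None


@dataclass
class CountMatrix:
    """Cells x features sparse integer count matrix with axis labels."""

    matrix: sparse.csr_matrix
    barcodes: list[str]
    features: list[str]

    def __post_init__(self) -> None:
        self.matrix = sparse.csr_matrix(self.matrix)
        if self.matrix.shape != (len(self.barcodes), len(self.features)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.barcodes)} barcodes x {len(self.features)} features"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("duplicate barcodes")
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def row_totals(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=1)).ravel()

    def subset_cells(self, keep: Sequence[str] | np.ndarray) -> "CountMatrix":
        """Return a new matrix restricted to the given barcodes (or boolean mask)."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {b: i for i, b in enumerate(self.barcodes)}
            idx = np.array([pos[b] for b in keep], dtype=int)
        return CountMatrix(
            self.matrix[idx], [self.barcodes[i] for i in idx], list(self.features)
        )


def _open_text(path: Path | str, mode: str = "rt") -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_guide_reference(path: Path | str) -> list[GuideReference]:
    """Read a delimited guide table (columns guide_id, spacer, scaffold).

    The scaffold column may repeat a single shared value.  full_sequence is
    the concatenation spacer + scaffold.  Duplicate guide ids or non-ACGTN
    sequences raise ``ValueError`` naming the offending row.
    """
    with _open_text(path) as fh:
        table = pd.read_csv(fh, sep=None, engine="python")
    required = {"guide_id", "spacer", "scaffold"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"guide reference is missing columns: {sorted(missing)}")
    refs: list[GuideReference] = []
    seen: set[str] = set()
    for row_no, row in enumerate(table.itertuples(index=False), start=2):
        gid = str(row.guide_id)
        if gid in seen:
            raise ValueError(f"duplicate guide_id {gid!r} at row {row_no}")
        seen.add(gid)
        spacer = str(row.spacer).upper()
        scaffold = str(row.scaffold).upper()
        try:
            refs.append(GuideReference(gid, spacer, spacer + scaffold))
        except ValueError as exc:
            raise ValueError(f"row {row_no}: {exc}") from exc
    return refs


def write_guide_reference(refs: Sequence[GuideReference], path: Path | str) -> None:
    rows = [
        {
            "guide_id": r.guide_id,
            "spacer": r.spacer,
            "scaffold": r.full_sequence[len(r.spacer):],
        }
        for r in refs
    ]
    with _open_text(path, "wt") as fh:
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def read_tagged_fastq(
    r1_path: Path | str,
    r2_path: Path | str,
    barcode_len: int,
    umi_len: int,
) -> Iterator[TaggedRead]:
    """Stream paired FASTQ records as :class:`TaggedRead`.

    Read 1 carries the cell barcode (first ``barcode_len`` bases) followed by
    the UMI (next ``umi_len`` bases); read 2 is the cDNA sequence.  Records
    are paired in file order; unpaired trailing records raise; read-1
    records shorter than ``barcode_len + umi_len`` are skipped with a logged
    count.
    """
    min_len = barcode_len + umi_len
    n_skipped = 0
    with _open_text(r1_path) as fh1, _open_text(r2_path) as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        sentinel = object()
        while True:
            rec1 = next(it1, sentinel)
            rec2 = next(it2, sentinel)
            if rec1 is sentinel and rec2 is sentinel:
                break
            if rec1 is sentinel or rec2 is sentinel:
                raise ValueError(
                    f"unpaired FASTQ records: {r1_path} and {r2_path} differ in length"
                )
            (title1, seq1, _q1) = rec1
            (title2, seq2, q2) = rec2
            if len(seq1) < min_len:
                n_skipped += 1
                continue
            yield TaggedRead(
                cell_barcode=seq1[:barcode_len],
                umi=seq1[barcode_len : barcode_len + umi_len],
                sequence=seq2,
                quality=q2,
                read_id=title1.split()[0],
            )
    if n_skipped:
        logger.warning("read_tagged_fastq: skipped %d short read-1 records", n_skipped)


def write_tagged_fastq(
    reads: Iterable[TaggedRead],
    r1_path: Path | str,
    r2_path: Path | str,
) -> int:
    """Write read pairs back out as FASTQ; returns the number of pairs written."""
    n = 0
    with _open_text(r1_path, "wt") as fh1, _open_text(r2_path, "wt") as fh2:
        for i, read in enumerate(reads):
            rid = read.read_id or f"read{i}"
            seq1 = read.cell_barcode + read.umi
            fh1.write(f"@{rid}\n{seq1}\n+\n{'I' * len(seq1)}\n")
            qual = read.quality or "I" * len(read.sequence)
            fh2.write(f"@{rid}\n{read.sequence}\n+\n{qual}\n")
            n += 1
    return n


def _resolve_triplet_paths(
    dir_or_paths: Path | str | tuple,
) -> tuple[Path, Path, Path]:
    if isinstance(dir_or_paths, (tuple, list)):
        mtx, bc, ft = (Path(p) for p in dir_or_paths)
        return mtx, bc, ft
    d = Path(dir_or_paths)
    paths = []
    for stem in ("matrix.mtx", "barcodes.tsv", "features.tsv"):
        plain, gz = d / stem, d / (stem + ".gz")
        if plain.exists():
            paths.append(plain)
        elif gz.exists():
            paths.append(gz)
        else:
            raise FileNotFoundError(f"{stem}[.gz] not found in {d}")
    return tuple(paths)  # type: ignore[return-value]


def read_mtx_triplet(dir_or_paths: Path | str | tuple) -> CountMatrix:
    """Read a 10x-style MTX triplet into a cells x features :class:`CountMatrix`.

    Accepts a directory holding matrix.mtx / barcodes.tsv / features.tsv
    (optionally gzipped) or an explicit (matrix, barcodes, features) tuple.
    """
    mtx_path, bc_path, ft_path = _resolve_triplet_paths(dir_or_paths)
    with _open_text(mtx_path, "rt") as fh:
        mat = scipy_io.mmread(fh)
    if not np.issubdtype(np.asarray(mat.data).dtype, np.integer):
        if not np.allclose(mat.data, np.round(mat.data)):
            raise ValueError(f"{mtx_path}: non-integer entries in count matrix")
        mat = mat.astype(np.int64)
    with _open_text(bc_path) as fh:
        barcodes = [line.strip().split("\t")[0] for line in fh if line.strip()]
    with _open_text(ft_path) as fh:
        features = [line.strip().split("\t")[0] for line in fh if line.strip()]
    if mat.shape != (len(features), len(barcodes)):
        raise ValueError(
            f"dimension mismatch: matrix is {mat.shape} but there are "
            f"{len(features)} features and {len(barcodes)} barcodes"
        )
    return CountMatrix(sparse.csr_matrix(mat.T), barcodes, features)


def write_mtx_triplet(cm: CountMatrix, out_dir: Path | str) -> None:
    """Write a :class:`CountMatrix` as a 10x-style triplet (features x barcodes)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    disk = sparse.coo_matrix(cm.matrix.T.astype(np.int64))
    with open(out / "matrix.mtx", "wb") as fh:
        scipy_io.mmwrite(fh, disk, field="integer")
    with open(out / "barcodes.tsv", "wt") as fh:
        fh.write("\n".join(cm.barcodes) + ("\n" if cm.barcodes else ""))
    with open(out / "features.tsv", "wt") as fh:
        fh.write("\n".join(f"{f}\t{f}" for f in cm.features) + ("\n" if cm.features else ""))


def write_table(df: pd.DataFrame, path: Path | str, header_lines: Sequence[str] = ()) -> None:
    """Write a TSV with optional ``#``-prefixed comment header lines."""
    with _open_text(path, "wt") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: Path | str) -> pd.DataFrame:
    with _open_text(path) as fh:
        return pd.read_csv(fh, sep="\t", comment="#")
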