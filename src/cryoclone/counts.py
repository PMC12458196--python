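"""Strand-specific mitochondrial base-count tensor and its on-disk dialects.

The central object is :class:`StrandBaseCounts`: a sparse
``barcode x position x base x strand`` tensor of non-negative integer read
counts, with per-(barcode, position) coverage derived as the sum over the
four bases and both strands.

On-disk dialects
----------------
* Per-base tables ``A.txt``/``C.txt``/``G.txt``/``T.txt``: CSV, no header,
  columns ``position,barcode_index,fwd,rev`` (1-based position and
  barcode index).
* ``coverage.txt``: CSV, no header, ``position,barcode_index,coverage``.
* ``barcodes.txt``: one barcode per line, defining the index order.
* Quad-matrix export: MatrixMarket ``matrix.mtx`` + ``features.tsv`` +
  ``barcodes.tsv``, four feature rows per variant in the fixed order
  ref-fwd, ref-rev, alt-fwd, alt-rev.

All public interfaces speak 1-based mitochondrial coordinates; storage is
0-based internally.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse

from .errors import ArgumentError, FormatError, IntegrityError, VariantLabelError

BASES = ("A", "C", "G", "T")
STRANDS = ("fwd", "rev")
HUMAN_MT_LENGTH = 16_569
MOUSE_MT_LENGTH = 16_299

_LABEL_RE = re.compile(r"^(?:mt\.|X)(\d+)([ACGT])>([ACGT])$")


@dataclass(frozen=True, order=True)
class Variant:
    """A single-nucleotide mitochondrial variant in 1-based coordinates."""

    position: int
    ref: str
    alt: str

    def __post_init__(self):
        if self.ref not in BASES or self.alt not in BASES:
            raise VariantLabelError(
                f"bases must be one of {BASES}: got ref={self.ref!r} alt={self.alt!r}"
            )
        if self.ref == self.alt:
            raise VariantLabelError(f"ref == alt ({self.ref}) at position {self.position}")
        if self.position < 1:
            raise VariantLabelError(f"position must be >= 1, got {self.position}")

    @property
    def label(self) -> str:
        """Canonical text rendering, e.g. ``mt.1206G>A``."""
        return f"mt.{self.position}{self.ref}>{self.alt}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def parse_variant_label(label: str, genome_length: int = HUMAN_MT_LENGTH) -> Variant:
    """Parse a variant label in either the ``mt.1206G>A`` or ``X301A>C`` dialect.

    Parameters
    ----------
    label
        Text label; the ``mt.`` and ``X`` prefixes are both accepted,
        ``mt.`` is canonical on output.
    genome_length
        Upper bound for the 1-based position.

    Raises
    ------
    VariantLabelError
        On malformed labels, out-of-range positions, or ``ref == alt``.
    """
    m = _LABEL_RE.match(label.strip())
    if m is None:
        raise VariantLabelError(f"malformed variant label: {label!r}")
    pos = int(m.group(1))
    if not 1 <= pos <= genome_length:
        raise VariantLabelError(
            f"position {pos} out of range [1, {genome_length}] in label {label!r}"
        )
    ref, alt = m.group(2), m.group(3)
    if ref == alt:
        raise VariantLabelError(f"ref == alt ({ref}) in label {label!r}")
    return Variant(pos, ref, alt)


@dataclass
class BarcodeRecord:
    """Per-barcode QC summary (``singlecell.csv`` dialect).

    Optional metrics absent from the input are ``None``, never 0.
    """

    barcode: str
    mito_fragments: int = 0
    peak_region_fragments: int = 0
    tss_enrichment: float | None = None
    nucleosome_signal: float | None = None
    n_count_peaks: int | None = None
    frip: float | None = None
    is_cell: bool | None = None

    def __post_init__(self):
        if self.mito_fragments < 0 or self.peak_region_fragments < 0:
            raise FormatError(f"negative fragment count for barcode {self.barcode}")
        if self.frip is not None and not 0.0 <= self.frip <= 1.0:
            raise FormatError(f"frip out of [0, 1] for barcode {self.barcode}: {self.frip}")


class StrandBaseCounts:
    """Sparse barcode x position x base x strand count tensor.

    Backed by eight CSR matrices (one per base/strand) of shape
    ``(n_barcodes, genome_length)``.
    """

    def __init__(
        self,
        barcodes: Sequence[str],
        genome_length: int,
        matrices: Mapping[tuple[str, str], sparse.spmatrix] | None = None,
    ):
        if genome_length < 1:
            raise ArgumentError(f"genome_length must be positive, got {genome_length}")
        if len(set(barcodes)) != len(barcodes):
            raise ArgumentError("duplicate barcodes in tensor")
        self.barcodes: list[str] = list(barcodes)
        self.genome_length = int(genome_length)
        self._index = {b: i for i, b in enumerate(self.barcodes)}
        shape = (len(self.barcodes), self.genome_length)
        self._mats: dict[tuple[str, str], sparse.csr_matrix] = {}
        for base in BASES:
            for strand in STRANDS:
                key = (base, strand)
                if matrices is not None and key in matrices:
                    m = sparse.csr_matrix(matrices[key], dtype=np.int64)
                    if m.shape != shape:
                        raise ArgumentError(
                            f"matrix for {key} has shape {m.shape}, expected {shape}"
                        )
                    if m.nnz and m.data.min() < 0:
                        raise FormatError(f"negative counts in {key} matrix")
                    m.eliminate_zeros()
                else:
                    m = sparse.csr_matrix(shape, dtype=np.int64)
                self._mats[key] = m
        self._coverage: sparse.csr_matrix | None = None

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_entries(
        cls,
        barcodes: Sequence[str],
        genome_length: int,
        entries: Iterable[tuple[str, int, str, str, int]],
    ) -> "StrandBaseCounts":
        """Build from ``(barcode, position(1-based), base, strand, count)`` tuples."""
        index = {b: i for i, b in enumerate(barcodes)}
        rows: dict[tuple[str, str], list[int]] = {(b, s): [] for b in BASES for s in STRANDS}
        cols: dict[tuple[str, str], list[int]] = {(b, s): [] for b in BASES for s in STRANDS}
        vals: dict[tuple[str, str], list[int]] = {(b, s): [] for b in BASES for s in STRANDS}
        for bc, pos, base, strand, count in entries:
            if bc not in index:
                raise FormatError(f"unknown barcode {bc!r}")
            if not 1 <= pos <= genome_length:
                raise FormatError(f"position {pos} out of range [1, {genome_length}]")
            if count < 0:
                raise FormatError(f"negative count at ({bc}, {pos}, {base}, {strand})")
            key = (base, strand)
            if key not in rows:
                raise FormatError(f"invalid base/strand {key}")
            rows[key].append(index[bc])
            cols[key].append(pos - 1)
            vals[key].append(count)
        shape = (len(barcodes), genome_length)
        mats = {
            key: sparse.coo_matrix((vals[key], (rows[key], cols[key])), shape=shape)
            for key in rows
        }
        return cls(barcodes, genome_length, mats)

    # -- accessors ------------------------------------------------------------

    def matrix(self, base: str, strand: str) -> sparse.csr_matrix:
        """The (n_barcodes, genome_length) CSR matrix for one base/strand."""
        return self._mats[(base, strand)]

    def barcode_index(self, barcode: str) -> int:
        try:
            return self._index[barcode]
        except KeyError:
            raise ArgumentError(f"barcode {barcode!r} not in tensor") from None

    def count(self, barcode: str, position: int, base: str, strand: str) -> int:
        """Single count lookup, 1-based position."""
        i = self.barcode_index(barcode)
        return int(self._mats[(base, strand)][i, position - 1])

    def coverage_matrix(self) -> sparse.csr_matrix:
        """Coverage = sum over the four bases and both strands, cached."""
        if self._coverage is None:
            total = None
            for m in self._mats.values():
                total = m.copy() if total is None else total + m
            self._coverage = sparse.csr_matrix(total)
        return self._coverage

    def coverage(self, barcode: str, position: int) -> int:
        i = self.barcode_index(barcode)
        return int(self.coverage_matrix()[i, position - 1])

    def position_counts(self, position: int, base: str) -> tuple[np.ndarray, np.ndarray]:
        """Per-barcode (fwd, rev) count vectors for one base at a 1-based position."""
        col = position - 1
        fwd = np.asarray(self._mats[(base, "fwd")][:, col].todense()).ravel()
        rev = np.asarray(self._mats[(base, "rev")][:, col].todense()).ravel()
        return fwd, rev

    def total_counts(self) -> int:
        return int(sum(int(m.sum()) for m in self._mats.values()))

    def subset(self, barcodes: Sequence[str]) -> "StrandBaseCounts":
        """Row-subset to the given barcodes, preserving the given order."""
        idx = np.array([self.barcode_index(b) for b in barcodes], dtype=int)
        mats = {key: m[idx] for key, m in self._mats.items()}
        return StrandBaseCounts(list(barcodes), self.genome_length, mats)

    def copy(self) -> "StrandBaseCounts":
        return StrandBaseCounts(
            self.barcodes, self.genome_length, {k: m.copy() for k, m in self._mats.items()}
        )

    def equals(self, other: "StrandBaseCounts") -> bool:
        if self.barcodes != other.barcodes or self.genome_length != other.genome_length:
            return False
        return all(
            (self._mats[k] - other._mats[k]).nnz == 0 for k in self._mats
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"StrandBaseCounts(n_barcodes={len(self.barcodes)}, "
            f"genome_length={self.genome_length}, total={self.total_counts()})"
        )


# -- mgatk-dialect reader/writer ---------------------------------------------


def _read_table(path: Path, n_cols: int) -> np.ndarray:
    """Read a headerless CSV of non-negative integers with `n_cols` columns."""
    text = Path(path).read_text()
    if not text.strip():
        return np.empty((0, n_cols), dtype=np.int64)
    try:
        arr = np.loadtxt(io.StringIO(text), delimiter=",", dtype=np.int64, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if arr.shape[1] != n_cols:
        raise FormatError(f"{path}: expected {n_cols} columns, found {arr.shape[1]}")
    if arr.size and arr.min() < 0:
        raise FormatError(f"{path}: negative values present")
    return arr


def read_strand_counts(counts_dir: str | Path, prefix: str = "") -> StrandBaseCounts:
    """Read mgatk-dialect tables from a directory.

    Expects ``{prefix}A.txt``, ``C.txt``, ``G.txt``, ``T.txt`` with columns
    ``position,barcode_index,fwd,rev``; ``{prefix}coverage.txt`` with
    ``position,barcode_index,coverage``; and ``{prefix}barcodes.txt``.
    The derived coverage must equal the coverage table exactly.
    """
    counts_dir = Path(counts_dir)
    barcodes_path = counts_dir / f"{prefix}barcodes.txt"
    barcodes = [ln.strip() for ln in barcodes_path.read_text().splitlines() if ln.strip()]
    if len(set(barcodes)) != len(barcodes):
        raise FormatError(f"{barcodes_path}: duplicate barcodes")
    cov_arr = _read_table(counts_dir / f"{prefix}coverage.txt", 3)
    genome_length = _infer_genome_length(counts_dir, prefix, cov_arr)

    n = len(barcodes)
    mats = {}
    for base in BASES:
        arr = _read_table(counts_dir / f"{prefix}{base}.txt", 4)
        if arr.size:
            pos, bidx = arr[:, 0], arr[:, 1]
            if pos.min() < 1 or pos.max() > genome_length:
                raise FormatError(f"{base}.txt: position out of range [1, {genome_length}]")
            if bidx.min() < 1 or bidx.max() > n:
                raise FormatError(f"{base}.txt: barcode index out of range [1, {n}]")
        shape = (n, genome_length)
        for si, strand in enumerate(STRANDS):
            if arr.size:
                m = sparse.coo_matrix(
                    (arr[:, 2 + si], (arr[:, 1] - 1, arr[:, 0] - 1)), shape=shape
                )
            else:
                m = sparse.coo_matrix(shape, dtype=np.int64)
            mats[(base, strand)] = m
    tensor = StrandBaseCounts(barcodes, genome_length, mats)

    # integrity: derived coverage must match the supplied coverage table
    shape = (n, genome_length)
    if cov_arr.size:
        supplied = sparse.coo_matrix(
            (cov_arr[:, 2], (cov_arr[:, 1] - 1, cov_arr[:, 0] - 1)), shape=shape
        ).tocsr()
    else:
        supplied = sparse.csr_matrix(shape, dtype=np.int64)
    diff = (tensor.coverage_matrix() - supplied).tocoo()
    if diff.nnz:
        order = np.lexsort((diff.col, diff.row))
        i, j = int(diff.row[order[0]]), int(diff.col[order[0]])
        raise IntegrityError(
            "coverage table disagrees with base counts; first mismatch at "
            f"(barcode={barcodes[i]!r}, position={j + 1})"
        )
    return tensor


def _infer_genome_length(counts_dir: Path, prefix: str, cov_arr: np.ndarray) -> int:
    meta = counts_dir / f"{prefix}genome_length.txt"
    if meta.exists():
        return int(meta.read_text().strip())
    max_pos = int(cov_arr[:, 0].max()) if cov_arr.size else 1
    return max(max_pos, HUMAN_MT_LENGTH) if max_pos > MOUSE_MT_LENGTH else HUMAN_MT_LENGTH


def write_strand_counts(tensor: StrandBaseCounts, out_dir: str | Path, prefix: str = "") -> list[Path]:
    """Write mgatk-dialect tables; byte-deterministic for a fixed tensor.

    Rows are ordered position-ascending then barcode-index-ascending. A
    ``genome_length.txt`` sidecar makes round-trips exact for non-default
    genome lengths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    path = out_dir / f"{prefix}barcodes.txt"
    path.write_text("".join(f"{b}\n" for b in tensor.barcodes))
    written.append(path)
    path = out_dir / f"{prefix}genome_length.txt"
    path.write_text(f"{tensor.genome_length}\n")
    written.append(path)

    def _dump(path: Path, rows: np.ndarray) -> None:
        # rows: (pos0, bidx0, v1[, v2]); emitted 1-based, sorted
        with path.open("w") as fh:
            for row in rows:
                fh.write(",".join(str(int(x)) for x in row) + "\n")
        written.append(path)

    for base in BASES:
        fwd = tensor.matrix(base, "fwd").tocoo()
        rev = tensor.matrix(base, "rev").tocoo()
        # union of nonzero cells across strands
        keys = {(int(c), int(r)) for r, c in zip(fwd.row, fwd.col)}
        keys |= {(int(c), int(r)) for r, c in zip(rev.row, rev.col)}
        fcsr, rcsr = tensor.matrix(base, "fwd"), tensor.matrix(base, "rev")
        out_rows = []
        for pos0, bidx0 in sorted(keys):
            out_rows.append(
                (pos0 + 1, bidx0 + 1, int(fcsr[bidx0, pos0]), int(rcsr[bidx0, pos0]))
            )
        _dump(out_dir / f"{prefix}{base}.txt", np.array(out_rows, dtype=np.int64).reshape(-1, 4))

    cov = tensor.coverage_matrix().tocoo()
    order = np.lexsort((cov.row, cov.col))
    cov_rows = np.column_stack(
        [cov.col[order] + 1, cov.row[order] + 1, cov.data[order]]
    ) if cov.nnz else np.empty((0, 3), dtype=np.int64)
    _dump(out_dir / f"{prefix}coverage.txt", cov_rows)
    return written


# -- quad-matrix export -------------------------------------------------------

QUAD_FEATURE_ORDER = ("ref_fwd", "ref_rev", "alt_fwd", "alt_rev")


def variant_quad_matrix(
    tensor: StrandBaseCounts,
    variants: Sequence[Variant],
    barcodes: Sequence[str] | None = None,
) -> tuple[sparse.csr_matrix, list[str]]:
    """Build the 4-rows-per-variant count matrix (features x barcodes).

    Per variant the rows are ref-fwd, ref-rev, alt-fwd, alt-rev; feature
    names are ``{label}:{slot}``.
    """
    if not variants:
        raise ArgumentError("variants must be non-empty")
    if len(set(variants)) != len(variants):
        raise ArgumentError("duplicate variants in quad-matrix export")
    if barcodes is None:
        barcodes = tensor.barcodes
    idx = np.array([tensor.barcode_index(b) for b in barcodes], dtype=int)
    blocks = []
    names: list[str] = []
    for v in variants:
        if not 1 <= v.position <= tensor.genome_length:
            raise ArgumentError(f"variant {v.label} out of range")
        col = v.position - 1
        for slot, (base, strand) in zip(
            QUAD_FEATURE_ORDER,
            [(v.ref, "fwd"), (v.ref, "rev"), (v.alt, "fwd"), (v.alt, "rev")],
        ):
            blocks.append(tensor.matrix(base, strand)[idx, col].T)
            names.append(f"{v.label}:{slot}")
    mat = sparse.vstack([sparse.csr_matrix(b) for b in blocks], format="csr")
    return mat, names


def export_variant_quad_matrix(
    tensor: StrandBaseCounts,
    variants: Sequence[Variant],
    out_dir: str | Path,
    barcodes: Sequence[str] | None = None,
) -> tuple[Path, Path, Path]:
    """Write the quad matrix as legacy 10x-style MatrixMarket triplets."""
    from scipy.io import mmwrite

    if barcodes is None:
        barcodes = tensor.barcodes
    mat, names = variant_quad_matrix(tensor, variants, barcodes)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mtx = out_dir / "matrix.mtx"
    mmwrite(str(mtx), sparse.coo_matrix(mat), field="integer")
    feats = out_dir / "features.tsv"
    feats.write_text("".join(f"{n}\n" for n in names))
    bcs = out_dir / "barcodes.tsv"
    bcs.write_text("".join(f"{b}\n" for b in barcodes))
    return mtx, feats, bcs


# -- barcode summary reader ---------------------------------------------------

# 1-based positional column indices in the singlecell.csv dialect
_POSITIONAL_COLUMNS = {"mito_fragments": 7, "peak_region_fragments": 18}

_NAMED_ALIASES = {
    "barcode": "barcode",
    "mito_fragments": "mito_fragments",
    "mitochondrial": "mito_fragments",
    "peak_region_fragments": "peak_region_fragments",
    "tss_enrichment": "tss_enrichment",
    "TSS.enrichment": "tss_enrichment",
    "nucleosome_signal": "nucleosome_signal",
    "NucleosomeSignal": "nucleosome_signal",
    "n_count_peaks": "n_count_peaks",
    "nCount_peaks": "n_count_peaks",
    "frip": "frip",
    "FRiP": "frip",
    "is_cell": "is_cell",
    "is__cell_barcode": "is_cell",
}


def read_barcode_summary(path: str | Path, dialect: str = "named") -> list[BarcodeRecord]:
    """Read a per-barcode QC summary table.

    ``dialect="positional"`` follows the singlecell.csv convention: barcode in
    column 1, mitochondrial fragment count in column 7 and
    ``peak_region_fragments`` in column 18 (1-based). ``dialect="named"``
    requires a header row and maps recognized column names.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    records: list[BarcodeRecord] = []
    if dialect == "positional":
        start = 0
        if lines and not _looks_numeric(lines[0].split(",")[6:7]):
            start = 1  # tolerate a header row
        for lineno, ln in enumerate(lines[start:], start=start + 1):
            fields = ln.split(",")
            if len(fields) < 18:
                raise FormatError(
                    f"{path}:{lineno}: positional dialect needs >= 18 columns, found {len(fields)}"
                )
            records.append(
                BarcodeRecord(
                    barcode=fields[0],
                    mito_fragments=int(float(fields[_POSITIONAL_COLUMNS["mito_fragments"] - 1])),
                    peak_region_fragments=int(
                        float(fields[_POSITIONAL_COLUMNS["peak_region_fragments"] - 1])
                    ),
                )
            )
        return records
    if dialect != "named":
        raise ArgumentError(f"unknown dialect {dialect!r}")
    if not lines:
        return records
    header = lines[0].split(",")
    colmap: dict[int, str] = {}
    for i, name in enumerate(header):
        key = _NAMED_ALIASES.get(name.strip())
        if key:
            colmap[i] = key
    if "barcode" not in colmap.values():
        raise FormatError(f"{path}: named dialect requires a 'barcode' column")
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = ln.split(",")
        kwargs: dict = {}
        for i, key in colmap.items():
            if i >= len(fields) or fields[i] == "":
                continue
            raw = fields[i]
            if key == "barcode":
                kwargs[key] = raw
            elif key == "is_cell":
                kwargs[key] = raw.strip() in ("1", "True", "true", "TRUE")
            elif key in ("mito_fragments", "peak_region_fragments", "n_count_peaks"):
                kwargs[key] = int(float(raw))
            else:
                kwargs[key] = float(raw)
        try:
            records.append(BarcodeRecord(**kwargs))
        except TypeError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return records


def _looks_numeric(fields: list[str]) -> bool:
    try:
        [float(f) for f in fields]
        return True
    except (ValueError, TypeError):
        return False


def write_barcode_summary(records: Sequence[BarcodeRecord], path: str | Path) -> Path:
    """Write records in the named dialect (all fields, blanks for absent)."""
    path = Path(path)
    cols = [
        "barcode",
        "mito_fragments",
        "peak_region_fragments",
        "tss_enrichment",
        "nucleosome_signal",
        "n_count_peaks",
        "frip",
        "is_cell",
    ]
    with path.open("w") as fh:
        fh.write(",".join(cols) + "\n")
        for r in records:
            vals = []
            for c in cols:
                v = getattr(r, c)
                if v is None:
                    vals.append("")
                elif isinstance(v, bool):
                    vals.append("1" if v else "0")
                elif isinstance(v, float):
                    vals.append(repr(v))
                else:
                    vals.append(str(v))
            fh.write(",".join(vals) + "\n")
    return path
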