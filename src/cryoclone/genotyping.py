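"""Per-cell heteroplasmy, variant confidence metrics, pseudobulk summaries,
substitution spectra and variant-set overlaps.

Heteroplasmy (VAF) of variant v in cell b is
``(alt_fwd + alt_rev) / coverage`` at v's position; entries with zero
coverage are missing, not zero. Variant confidence follows the
mgatk-style metric family: number of confidently detected cells, strand
concordance (Pearson correlation of per-cell forward vs reverse alternate
read counts), mean coverage, and the log10 variance-to-mean ratio of
per-cell heteroplasmy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .counts import BASES, StrandBaseCounts, Variant
from .errors import ArgumentError

#: Known artifact-prone positions removed by default before lineage analyses.
DEFAULT_ARTIFACT_BLOCKLIST: tuple[Variant, ...] = (
    Variant(301, "A", "C"),
    Variant(302, "A", "C"),
    Variant(309, "C", "T"),
    Variant(310, "T", "C"),
    Variant(316, "G", "C"),
    Variant(3109, "T", "C"),
    Variant(189, "A", "G"),
)


class HeteroplasmyMatrix:
    """Cells x variants allele-fraction matrix with per-entry coverage.

    ``af`` is 0 and ``missing`` is True wherever coverage is 0.
    """

    def __init__(
        self,
        cells: Sequence[str],
        variants: Sequence[Variant],
        af: np.ndarray,
        cov: np.ndarray,
        alt_fwd: np.ndarray | None = None,
        alt_rev: np.ndarray | None = None,
    ):
        n, m = len(cells), len(variants)
        af = np.asarray(af, dtype=float)
        cov = np.asarray(cov, dtype=np.int64)
        if af.shape != (n, m) or cov.shape != (n, m):
            raise ArgumentError(f"af/cov shape must be ({n}, {m})")
        if np.any(af < 0) or np.any(af > 1):
            raise ArgumentError("allele fractions must lie in [0, 1]")
        if np.any(af[cov == 0] != 0):
            raise ArgumentError("af must be 0 where coverage is 0")
        self.cells = list(cells)
        self.variants = list(variants)
        self.af = af
        self.cov = cov
        self.alt_fwd = None if alt_fwd is None else np.asarray(alt_fwd, dtype=np.int64)
        self.alt_rev = None if alt_rev is None else np.asarray(alt_rev, dtype=np.int64)
        self._cell_index = {c: i for i, c in enumerate(self.cells)}
        self._var_index = {v: j for j, v in enumerate(self.variants)}

    @property
    def missing(self) -> np.ndarray:
        return self.cov == 0

    @property
    def alt_total(self) -> np.ndarray:
        if self.alt_fwd is not None and self.alt_rev is not None:
            return self.alt_fwd + self.alt_rev
        return np.rint(self.af * self.cov).astype(np.int64)

    def cell_index(self, cell: str) -> int:
        return self._cell_index[cell]

    def variant_index(self, variant: Variant) -> int:
        return self._var_index[variant]

    def subset_cells(self, cells: Sequence[str]) -> "HeteroplasmyMatrix":
        idx = [self._cell_index[c] for c in cells]
        return HeteroplasmyMatrix(
            list(cells),
            self.variants,
            self.af[idx],
            self.cov[idx],
            None if self.alt_fwd is None else self.alt_fwd[idx],
            None if self.alt_rev is None else self.alt_rev[idx],
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"HeteroplasmyMatrix({len(self.cells)} cells x {len(self.variants)} variants)"


def compute_heteroplasmy(
    tensor: StrandBaseCounts,
    variants: Sequence[Variant],
    cells: Sequence[str] | None = None,
) -> HeteroplasmyMatrix:
    """Per-cell allele frequencies from strand-specific counts over coverage."""
    if cells is None:
        cells = tensor.barcodes
    idx = np.array([tensor.barcode_index(b) for b in cells], dtype=int)
    n, m = len(cells), len(variants)
    af = np.zeros((n, m), dtype=float)
    cov = np.zeros((n, m), dtype=np.int64)
    altf = np.zeros((n, m), dtype=np.int64)
    altr = np.zeros((n, m), dtype=np.int64)
    covmat = tensor.coverage_matrix()
    for j, v in enumerate(variants):
        col = v.position - 1
        altf[:, j] = np.asarray(tensor.matrix(v.alt, "fwd")[idx, col].todense()).ravel()
        altr[:, j] = np.asarray(tensor.matrix(v.alt, "rev")[idx, col].todense()).ravel()
        cov[:, j] = np.asarray(covmat[idx, col].todense()).ravel()
    covered = cov > 0
    af[covered] = (altf[covered] + altr[covered]) / cov[covered]
    # conservation guard: alt reads can never exceed coverage
    assert np.all(altf + altr <= cov), "alternate reads exceed coverage"
    return HeteroplasmyMatrix(cells, list(variants), af, cov, altf, altr)


def call_candidate_variants(
    tensor: StrandBaseCounts,
    reference: str,
    cells: Sequence[str] | None = None,
) -> list[Variant]:
    """Enumerate every (position, alt != ref) with at least one alternate read.

    Positions whose reference base is ``N`` are skipped. Sorted by
    (position, alt base).
    """
    reference = reference.upper()
    if len(reference) != tensor.genome_length:
        raise ArgumentError(
            f"reference length {len(reference)} != genome length {tensor.genome_length}"
        )
    if cells is None:
        sub = tensor
    else:
        sub = tensor.subset(list(cells))
    found: set[Variant] = set()
    for base in BASES:
        total = (sub.matrix(base, "fwd") + sub.matrix(base, "rev")).tocsc()
        cols = np.unique(total.nonzero()[1])
        for col in cols:
            ref = reference[col]
            if ref == "N" or ref == base:
                continue
            if ref not in BASES:
                continue
            found.add(Variant(int(col) + 1, ref, base))
    return sorted(found, key=lambda v: (v.position, v.alt))


@dataclass
class VariantMetrics:
    """Per-variant confidence statistics; undefined metrics are ``None``/NaN."""

    variant: Variant
    n_cells_conf_detected: int
    strand_concordance: float | None
    mean_coverage: float
    log10_vmr: float | None
    pseudobulk_het_mean: float
    pseudobulk_het_aggregate: float
    n_cells_over_threshold: int


def compute_variant_metrics(
    het: HeteroplasmyMatrix,
    conf_min_alt_per_strand: int = 1,
    conf_min_alt_total: int = 2,
    positivity_threshold: float = 0.20,
    ddof: int = 0,
) -> list[VariantMetrics]:
    """mgatk-style per-variant confidence metrics over QC-passing cells.

    * ``n_cells_conf_detected``: cells with >= ``conf_min_alt_per_strand``
      alternate reads on each strand and >= ``conf_min_alt_total`` in total.
    * ``strand_concordance``: Pearson correlation across cells (nonzero
      coverage) of forward vs reverse alternate counts; ``None`` if fewer
      than 2 cells carry alternate reads or either strand has zero variance.
    * ``log10_vmr``: log10 of variance(af)/mean(af) over non-missing cells
      (population variance by default); ``None`` when the mean is 0.
    """
    if het.alt_fwd is None or het.alt_rev is None:
        raise ArgumentError("strand-resolved alternate counts required for metrics")
    out: list[VariantMetrics] = []
    for j, v in enumerate(het.variants):
        cov = het.cov[:, j]
        af = het.af[:, j]
        fwd = het.alt_fwd[:, j]
        rev = het.alt_rev[:, j]
        covered = cov > 0

        conf = (fwd >= conf_min_alt_per_strand) & (rev >= conf_min_alt_per_strand) & (
            fwd + rev >= conf_min_alt_total
        )
        n_conf = int(np.count_nonzero(conf))

        concordance: float | None = None
        carrier = covered & ((fwd + rev) > 0)
        if np.count_nonzero(carrier) >= 2:
            x = fwd[covered].astype(float)
            y = rev[covered].astype(float)
            if np.ptp(x) > 0 and np.ptp(y) > 0:
                with np.errstate(invalid="ignore"):
                    concordance = float(np.corrcoef(x, y)[0, 1])
                if math.isnan(concordance):
                    concordance = None

        mean_cov = float(np.mean(cov)) if cov.size else 0.0

        log10_vmr: float | None = None
        af_nm = af[covered]
        if af_nm.size and af_nm.mean() > 0:
            vmr = float(np.var(af_nm, ddof=ddof)) / float(af_nm.mean())
            log10_vmr = float(np.log10(vmr)) if vmr > 0 else -math.inf

        pb_mean = float(af_nm.mean()) if af_nm.size else float("nan")
        total_cov = int(cov.sum())
        pb_agg = float((fwd + rev).sum() / total_cov) if total_cov else float("nan")

        n_over = int(np.count_nonzero(covered & (af > positivity_threshold)))
        out.append(
            VariantMetrics(
                variant=v,
                n_cells_conf_detected=n_conf,
                strand_concordance=concordance,
                mean_coverage=mean_cov,
                log10_vmr=log10_vmr,
                pseudobulk_het_mean=pb_mean,
                pseudobulk_het_aggregate=pb_agg,
                n_cells_over_threshold=n_over,
            )
        )
    return out


def filter_high_confidence(
    metrics: Sequence[VariantMetrics],
    min_cells: int = 5,
    min_concordance: float = 0.65,
    min_log10_vmr: float = -2.0,
    min_mean_cov: float = 5.0,
) -> list[Variant]:
    """High-confidence variant filter.

    Keep iff n_cells_conf_detected >= min_cells AND strand concordance
    strictly > min_concordance AND log10(VMR) strictly > min_log10_vmr AND
    mean coverage >= min_mean_cov. An undefined metric fails the filter.
    """
    kept = []
    for m in metrics:
        if m.n_cells_conf_detected < min_cells:
            continue
        if m.strand_concordance is None or not m.strand_concordance > min_concordance:
            continue
        if m.log10_vmr is None or not m.log10_vmr > min_log10_vmr:
            continue
        if not m.mean_coverage >= min_mean_cov:
            continue
        kept.append(m.variant)
    return kept


def drop_artifact_variants(
    variants: Iterable[Variant],
    blocklist: Iterable[Variant] = DEFAULT_ARTIFACT_BLOCKLIST,
) -> list[Variant]:
    """Remove known artifactual variants (set difference, order preserved)."""
    block = set(blocklist)
    return [v for v in variants if v not in block]


def pseudobulk_heteroplasmy(
    het: HeteroplasmyMatrix,
    groups: Mapping[str, str],
    mode: str = "mean",
) -> pd.DataFrame:
    """Variant x group pseudobulk heteroplasmy table.

    ``mode="mean"``: mean af over non-missing cells in the group.
    ``mode="aggregate"``: sum of alternate reads over sum of coverage.
    Groups with no covered cell for a variant are NaN.
    """
    if mode not in ("mean", "aggregate"):
        raise ArgumentError(f"unknown pseudobulk mode {mode!r}")
    missing_cells = [c for c in het.cells if c not in groups]
    if missing_cells:
        raise ArgumentError(f"{len(missing_cells)} cells lack a group label, e.g. {missing_cells[0]!r}")
    labels = sorted(set(groups[c] for c in het.cells))
    alt = het.alt_total
    data = np.full((len(het.variants), len(labels)), np.nan)
    cell_labels = np.array([groups[c] for c in het.cells])
    for gi, g in enumerate(labels):
        rows = cell_labels == g
        cov_g = het.cov[rows]
        covered = cov_g > 0
        if mode == "mean":
            af_g = het.af[rows]
            with np.errstate(invalid="ignore"):
                sums = np.where(covered, af_g, 0.0).sum(axis=0)
                ns = covered.sum(axis=0)
            data[:, gi] = np.where(ns > 0, sums / np.maximum(ns, 1), np.nan)
        else:
            tot_alt = alt[rows].sum(axis=0)
            tot_cov = cov_g.sum(axis=0)
            data[:, gi] = np.where(tot_cov > 0, tot_alt / np.maximum(tot_cov, 1), np.nan)
    return pd.DataFrame(data, index=[v.label for v in het.variants], columns=labels)


# 12 ordered substitution classes
SUBSTITUTION_CLASSES: tuple[str, ...] = tuple(
    f"{r}>{a}" for r in BASES for a in BASES if r != a
)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Pyrimidine-context collapse of the 12 classes into 6.
COLLAPSED_CLASSES: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


def substitution_spectrum(variants: Sequence[Variant]) -> pd.DataFrame:
    """Counts and proportions over the 12 substitution classes plus the
    6-class pyrimidine-context collapse (purine changes mapped to their
    reverse complement)."""
    counts = {cls: 0 for cls in SUBSTITUTION_CLASSES}
    for v in variants:
        counts[f"{v.ref}>{v.alt}"] += 1
    total = sum(counts.values())
    rows = []
    for cls in SUBSTITUTION_CLASSES:
        ref, alt = cls.split(">")
        collapsed = cls if ref in ("C", "T") else f"{_COMPLEMENT[ref]}>{_COMPLEMENT[alt]}"
        rows.append(
            {
                "class": cls,
                "collapsed_class": collapsed,
                "count": counts[cls],
                "proportion": counts[cls] / total if total else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("class")


def variant_set_overlap(sets: Mapping[str, Iterable[Variant]]) -> tuple[pd.DataFrame, dict[frozenset, int]]:
    """Venn-style membership table and per-combination intersection counts.

    Returns a boolean variant x group membership DataFrame and a dict
    mapping each non-empty group combination (frozenset of group names) to
    the number of variants found in exactly that combination; the counts
    partition the union.
    """
    groups = {g: set(vs) for g, vs in sets.items()}
    if not groups:
        raise ArgumentError("need at least one group")
    union = sorted(set().union(*groups.values()), key=lambda v: (v.position, v.alt))
    names = sorted(groups)
    member = pd.DataFrame(
        [[v in groups[g] for g in names] for v in union],
        index=[v.label for v in union],
        columns=names,
        dtype=bool,
    )
    combos: dict[frozenset, int] = {}
    for v in union:
        combo = frozenset(g for g in names if v in groups[g])
        combos[combo] = combos.get(combo, 0) + 1
    return member, combos
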