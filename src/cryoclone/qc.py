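"""Cell-level quality filtering, background-barcode ranking, and tissue score."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .counts import BarcodeRecord, StrandBaseCounts
from .errors import ArgumentError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Bound:
    """One inequality bound with explicit strictness.

    ``inclusive=False`` means the comparison is strict (``>`` for a lower
    bound, ``<`` for an upper bound).
    """

    value: float
    inclusive: bool = False

    def passes_lower(self, x: float) -> bool:
        return x >= self.value if self.inclusive else x > self.value

    def passes_upper(self, x: float) -> bool:
        return x <= self.value if self.inclusive else x < self.value


@dataclass(frozen=True)
class QCThresholdProfile:
    """Named set of per-cell QC bounds; ``None`` disables a bound.

    Lower bounds use :meth:`Bound.passes_lower`, upper bounds
    :meth:`Bound.passes_upper`. Strictness mirrors the inequality printed
    for each published profile.
    """

    name: str = "custom"
    min_mtdna_depth: Bound | None = Bound(5.0, inclusive=False)
    max_mtdna_depth: Bound | None = None
    min_tss: Bound | None = Bound(1.5, inclusive=False)
    max_tss: Bound | None = None
    min_fragments: Bound | None = None
    max_nucleosome_signal: Bound | None = None
    min_n_count_peaks: Bound | None = None
    max_n_count_peaks: Bound | None = None
    min_frip: Bound | None = None

    def __post_init__(self):
        for lo_name, hi_name in [
            ("min_mtdna_depth", "max_mtdna_depth"),
            ("min_tss", "max_tss"),
            ("min_n_count_peaks", "max_n_count_peaks"),
        ]:
            lo, hi = getattr(self, lo_name), getattr(self, hi_name)
            if lo is not None and hi is not None and lo.value >= hi.value:
                raise ArgumentError(f"{lo_name} must be < {hi_name}")


#: Published threshold profiles. Strictness follows the printed inequalities:
#: default "coverage > 5, TSS enrichment > 1.5"; als adds "mtDNA depth < 100"
#: and ">1,000" nuclear fragments; nb "nCount_peaks > 250 & < 20,000,
#: FRiP > 0.1, TSS > 1.5, NucleosomeSignal < 2"; aorta keeps cells with
#: >= 1,000 detected peaks, 2 < TSS < 10, nucleosome signal < 2, depth >= 5.
PROFILES: dict[str, QCThresholdProfile] = {
    "default": QCThresholdProfile(name="default"),
    "als": QCThresholdProfile(
        name="als",
        max_mtdna_depth=Bound(100.0, inclusive=False),
        min_fragments=Bound(1000, inclusive=False),
    ),
    "nb": QCThresholdProfile(
        name="nb",
        min_n_count_peaks=Bound(250, inclusive=False),
        max_n_count_peaks=Bound(20_000, inclusive=False),
        min_frip=Bound(0.1, inclusive=False),
        max_nucleosome_signal=Bound(2.0, inclusive=False),
    ),
    "aorta": QCThresholdProfile(
        name="aorta",
        min_mtdna_depth=Bound(5.0, inclusive=True),
        min_tss=Bound(2.0, inclusive=False),
        max_tss=Bound(10.0, inclusive=False),
        min_n_count_peaks=Bound(1000, inclusive=True),
        max_nucleosome_signal=Bound(2.0, inclusive=False),
    ),
}


def get_profile(name: str) -> QCThresholdProfile:
    try:
        return PROFILES[name]
    except KeyError:
        raise ArgumentError(
            f"unknown QC profile {name!r}; available: {sorted(PROFILES)}"
        ) from None


def per_cell_mtdna_depth(tensor: StrandBaseCounts) -> dict[str, float]:
    """Mean mitochondrial coverage per barcode: sum of coverage / genome length."""
    totals = np.asarray(tensor.coverage_matrix().sum(axis=1)).ravel()
    L = tensor.genome_length
    return {b: float(t) / L for b, t in zip(tensor.barcodes, totals)}


def filter_cells(
    records: Sequence[BarcodeRecord],
    depths: Mapping[str, float],
    profile: QCThresholdProfile,
) -> tuple[set[str], dict[str, list[str]]]:
    """Apply a threshold profile; returns (kept barcodes, failure reasons).

    Every violated bound is listed. A bound on a metric the record does not
    carry fails with reason ``missing_<metric>`` — absent is not zero.
    """
    kept: set[str] = set()
    reasons: dict[str, list[str]] = {}
    for rec in records:
        fails: list[str] = []
        depth = depths.get(rec.barcode)
        if profile.min_mtdna_depth is not None or profile.max_mtdna_depth is not None:
            if depth is None:
                fails.append("missing_mtdna_depth")
            else:
                if profile.min_mtdna_depth is not None and not profile.min_mtdna_depth.passes_lower(depth):
                    fails.append("mtdna_depth_low")
                if profile.max_mtdna_depth is not None and not profile.max_mtdna_depth.passes_upper(depth):
                    fails.append("mtdna_depth_high")
        _check(fails, "tss", rec.tss_enrichment, profile.min_tss, profile.max_tss)
        _check(fails, "fragments", rec.peak_region_fragments, profile.min_fragments, None)
        _check(fails, "nucleosome_signal", rec.nucleosome_signal, None, profile.max_nucleosome_signal)
        _check(fails, "n_count_peaks", rec.n_count_peaks, profile.min_n_count_peaks, profile.max_n_count_peaks)
        _check(fails, "frip", rec.frip, profile.min_frip, None)
        if fails:
            reasons[rec.barcode] = fails
        else:
            kept.add(rec.barcode)
    return kept, reasons


def _check(fails: list[str], name: str, value, lo: Bound | None, hi: Bound | None) -> None:
    if lo is None and hi is None:
        return
    if value is None:
        fails.append(f"missing_{name}")
        return
    if lo is not None and not lo.passes_lower(value):
        fails.append(f"{name}_low")
    if hi is not None and not hi.passes_upper(value):
        fails.append(f"{name}_high")


def rank_background_barcodes(
    records: Sequence[BarcodeRecord],
    top_n: int = 20_000,
    drop_zero_mito: bool = True,
) -> list[str]:
    """Top barcodes by ``peak_region_fragments`` for background genotyping.

    Sorted descending, ties broken by barcode lexicographic order, truncated
    to ``top_n``; barcodes with zero mitochondrial fragments are then removed
    (``drop_zero_mito=False`` keeps them).
    """
    if top_n <= 0:
        raise ArgumentError(f"top_n must be positive, got {top_n}")
    if not records:
        raise ArgumentError("records must be non-empty")
    ordered = sorted(records, key=lambda r: (-r.peak_region_fragments, r.barcode))
    top = ordered[:top_n]
    if drop_zero_mito:
        top = [r for r in top if r.mito_fragments > 0]
    if not top:
        warnings.warn("all ranked barcodes have zero mitochondrial fragments")
    return [r.barcode for r in top]


@dataclass(frozen=True)
class TissueScore:
    """Histology-based tissue integrity score from H&E assessment fractions."""

    intact: float
    necrosis: float
    freezing_artifacts: float

    @property
    def score(self) -> float:
        return (self.intact + (1.0 - self.necrosis) + (1.0 - self.freezing_artifacts)) / 3.0


def tissue_score(intact: float, necrosis: float, freezing_artifacts: float) -> TissueScore:
    """TS = (I + (1 - N) + (1 - FA)) / 3.

    Arguments may be fractions in [0, 1] or percentages in (1, 100]
    (auto-detected: any value > 1 switches all three to percent).
    """
    vals = [intact, necrosis, freezing_artifacts]
    if any(v > 1.0 for v in vals):
        vals = [v / 100.0 for v in vals]
    for name, v in zip(("I", "N", "FA"), vals):
        if not 0.0 <= v <= 1.0:
            raise ArgumentError(f"{name} out of range after normalization: {v}")
    return TissueScore(*vals)


def correlate_scores(
    ts_values: Sequence[float], qc_metric: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between tissue scores and a QC metric."""
    x = np.asarray(ts_values, dtype=float)
    y = np.asarray(qc_metric, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ArgumentError("inputs must be equal-length 1-D sequences")
    if x.size < 3:
        raise ArgumentError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ArgumentError("correlation undefined: zero variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
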