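import numpy as np
import pytest

from cryoclone.ambient import (
    correct_counts,
    estimate_ambient_profile,
    estimate_cell_ambient_fraction,
    remove_background,
    select_empty_droplets,
)
from cryoclone.counts import BarcodeRecord, StrandBaseCounts, Variant
from cryoclone.errors import ArgumentError, CryocloneError
from cryoclone.genotyping import HeteroplasmyMatrix, compute_heteroplasmy

from conftest import random_tensor


def _records(n_cells=5, n_empty=10, mito=20):
    recs = []
    for i in range(n_cells):
        recs.append(BarcodeRecord(f"cell{i}", mito_fragments=mito, peak_region_fragments=5000))
    for i in range(n_empty):
        recs.append(BarcodeRecord(f"emp{i}", mito_fragments=mito, peak_region_fragments=100))
    return recs


class TestSelectEmptyDroplets:
    def test_set_arithmetic(self):
        recs = _records()
        cells = {f"cell{i}" for i in range(5)}
        empties = select_empty_droplets(recs, cells, total_droplets=15)
        assert empties == {f"emp{i}" for i in range(10)}

    def test_low_count_exclusion(self):
        recs = _records(n_cells=1, n_empty=3, mito=1)
        with pytest.raises(CryocloneError, match="no background droplets"):
            select_empty_droplets(recs, {"cell0"}, total_droplets=10, low_count_threshold=1)

    def test_truncation_excludes_low_ranked(self):
        recs = _records(n_cells=2, n_empty=8)
        empties = select_empty_droplets(recs, {"cell0", "cell1"}, total_droplets=6)
        assert len(empties) == 4  # only 6 - 2 cells

    def test_simulator_truth_coverage(self):
        from cryoclone.simulate import simulate_mixing

        tensor, records, truth = simulate_mixing(
            seed=5, n_cells_per_donor=50, n_empty=300, genome_length=300
        )
        cells = set(truth.cells())
        empties = select_empty_droplets(records, cells, total_droplets=20_000)
        true_empty = {
            r.barcode
            for r in records
            if r.barcode not in cells and r.mito_fragments > 1
        }
        assert len(empties & true_empty) >= 0.95 * len(true_empty)


def _two_barcode_tensor():
    entries = [
        # emp0: all reads alt at pos 3
        ("emp0", 3, "T", "fwd", 20), ("emp0", 3, "T", "rev", 20),
        # emp1: all reads ref at pos 5
        ("emp1", 5, "G", "fwd", 50), ("emp1", 5, "G", "rev", 50),
    ]
    return StrandBaseCounts.from_entries(["emp0", "emp1"], 10, entries)


class TestEstimateAmbientProfile:
    def test_limits(self):
        tensor = _two_barcode_tensor()
        v_all_alt = Variant(3, "C", "T")
        v_no_alt = Variant(5, "G", "A")
        prof = estimate_ambient_profile(tensor, [v_all_alt, v_no_alt], {"emp0", "emp1"})
        assert prof.alpha[v_all_alt] == pytest.approx((40 + 0.5) / 41)
        assert prof.alpha[v_no_alt] == pytest.approx(0.5 / 101)

    def test_zero_coverage_flagged(self):
        tensor = _two_barcode_tensor()
        v = Variant(9, "A", "C")
        prof = estimate_ambient_profile(tensor, [v], {"emp0"})
        assert v in prof.undefined
        assert np.isnan(prof.alpha[v])

    def test_empty_set_rejected(self):
        with pytest.raises(ArgumentError):
            estimate_ambient_profile(_two_barcode_tensor(), [], set())

    def test_deterministic(self):
        tensor = _two_barcode_tensor()
        v = Variant(3, "C", "T")
        p1 = estimate_ambient_profile(tensor, [v], {"emp0", "emp1"})
        p2 = estimate_ambient_profile(tensor, [v], {"emp0", "emp1"})
        assert p1.alpha == p2.alpha


def _profile(alpha_map, empties=("e1",)):
    from cryoclone.ambient import AmbientProfile

    return AmbientProfile(alpha=dict(alpha_map), empty_droplets=set(empties),
                          total_ambient_reads=100, pseudocount=1.0)


class TestCellAmbientFraction:
    def test_zero_alt_gives_zero(self):
        v = Variant(2, "A", "G")
        het = HeteroplasmyMatrix(
            ["c1"], [v], np.array([[0.0]]), np.array([[50]]),
            alt_fwd=np.array([[0]]), alt_rev=np.array([[0]]),
        )
        rho = estimate_cell_ambient_fraction(het, _profile({v: 0.5}))
        assert rho["c1"] == 0.0

    def test_formula(self):
        # alpha=1, marker coverage 200, observed alt 10 -> rho 0.05
        v = Variant(2, "A", "G")
        het = HeteroplasmyMatrix(
            ["c1"], [v], np.array([[10 / 200]]), np.array([[200]]),
            alt_fwd=np.array([[5]]), alt_rev=np.array([[5]]),
        )
        rho = estimate_cell_ambient_fraction(het, _profile({v: 1.0}))
        assert rho["c1"] == pytest.approx(0.05)

    def test_no_markers_error(self):
        v = Variant(2, "A", "G")
        het = HeteroplasmyMatrix(
            ["c1"], [v], np.array([[0.0]]), np.array([[10]]),
            alt_fwd=np.array([[0]]), alt_rev=np.array([[0]]),
        )
        with pytest.raises(CryocloneError, match="marker"):
            estimate_cell_ambient_fraction(het, _profile({v: 0.001}))

    def test_fallback_median(self):
        v = Variant(2, "A", "G")
        af = np.array([[0.05], [0.05], [0.0]])
        cov = np.array([[100], [100], [0]])
        alt = np.array([[5], [5], [0]])
        het = HeteroplasmyMatrix(["c1", "c2", "c3"], [v], af, cov,
                                 alt_fwd=alt, alt_rev=np.zeros_like(alt))
        rho = estimate_cell_ambient_fraction(het, _profile({v: 0.5}))
        assert rho["c3"] == pytest.approx(np.median([rho["c1"], rho["c2"]]))


def _cell_tensor(cov=100, alt=6):
    ref = cov - alt
    entries = [
        ("c1", 4, "G", "fwd", ref // 2), ("c1", 4, "G", "rev", ref - ref // 2),
        ("c1", 4, "A", "fwd", alt // 2), ("c1", 4, "A", "rev", alt - alt // 2),
    ]
    return StrandBaseCounts.from_entries(["c1"], 10, entries)


class TestCorrectCounts:
    def test_rho_zero_identity(self):
        tensor = _cell_tensor()
        v = Variant(4, "G", "A")
        res = correct_counts(tensor, ["c1"], _profile({v: 1.0}), {"c1": 0.0})
        assert res.corrected.equals(tensor)
        assert res.total_removed == 0

    def test_alpha_zero_identity(self):
        tensor = _cell_tensor()
        v = Variant(4, "G", "A")
        res = correct_counts(tensor, ["c1"], _profile({v: 0.0}), {"c1": 0.5})
        assert res.corrected.equals(tensor)

    @pytest.mark.parametrize("rounding", ["entry", "apportion"])
    def test_expected_subtraction(self, rounding):
        # cov 100, k 6, rho .05, alpha 1 -> e = 5, k' = 1
        tensor = _cell_tensor(cov=100, alt=6)
        v = Variant(4, "G", "A")
        res = correct_counts(tensor, ["c1"], _profile({v: 1.0}), {"c1": 0.05},
                             rounding=rounding)
        corrected_alt = res.corrected.count("c1", 4, "A", "fwd") + res.corrected.count("c1", 4, "A", "rev")
        assert corrected_alt == 1
        assert res.removed[("c1", v)] == 5

    def test_reassign_preserves_coverage(self):
        tensor = _cell_tensor()
        v = Variant(4, "G", "A")
        res = correct_counts(tensor, ["c1"], _profile({v: 1.0}), {"c1": 0.05}, mode="reassign")
        assert res.corrected.coverage("c1", 4) == tensor.coverage("c1", 4)

    def test_drop_reduces_coverage_by_removed(self):
        tensor = _cell_tensor()
        v = Variant(4, "G", "A")
        res = correct_counts(tensor, ["c1"], _profile({v: 1.0}), {"c1": 0.05}, mode="drop")
        assert res.corrected.coverage("c1", 4) == tensor.coverage("c1", 4) - res.removed[("c1", v)]

    def test_removed_bounded_by_alt(self):
        tensor = _cell_tensor(cov=100, alt=3)
        v = Variant(4, "G", "A")
        res = correct_counts(tensor, ["c1"], _profile({v: 1.0}), {"c1": 0.5})
        assert res.removed[("c1", v)] <= 3
        alt_left = res.corrected.count("c1", 4, "A", "fwd") + res.corrected.count("c1", 4, "A", "rev")
        assert alt_left >= 0

    def test_monotone_in_rho_entry_mode(self):
        tensor = _cell_tensor(cov=100, alt=10)
        v = Variant(4, "G", "A")
        prev = 10
        for rho in (0.0, 0.02, 0.05, 0.08, 0.1, 0.5):
            res = correct_counts(tensor, ["c1"], _profile({v: 1.0}), {"c1": rho},
                                 rounding="entry")
            alt_left = res.corrected.count("c1", 4, "A", "fwd") + res.corrected.count("c1", 4, "A", "rev")
            assert alt_left <= prev
            prev = alt_left

    def test_strand_split_proportional(self):
        entries = [
            ("c1", 4, "G", "fwd", 50), ("c1", 4, "G", "rev", 50),
            ("c1", 4, "A", "fwd", 8), ("c1", 4, "A", "rev", 2),
        ]
        tensor = StrandBaseCounts.from_entries(["c1"], 10, entries)
        v = Variant(4, "G", "A")
        # e = 0.05 * 110 * 1 = 5.5 -> round 6, capped at 10? entry: min(10, 6)=6
        res = correct_counts(tensor, ["c1"], _profile({v: 1.0}), {"c1": 0.05},
                             rounding="entry")
        s = res.removed[("c1", v)]
        sf = 8 - res.corrected.count("c1", 4, "A", "fwd")
        sr = 2 - res.corrected.count("c1", 4, "A", "rev")
        assert sf + sr == s
        assert sf >= sr  # more removed from the heavier strand


class TestRemoveBackground:
    def _setup(self, rho):
        from cryoclone.simulate import simulate_mixing

        return simulate_mixing(
            seed=21, n_cells_per_donor=60, n_empty=400, genome_length=300,
            ambient_rho=rho,
        )

    def test_rho_zero_near_identity(self):
        tensor, records, truth = self._setup(rho=0.0)
        cells = truth.cells()
        variants = sorted(truth.variant_origin, key=lambda v: v.position)
        result, report = remove_background(tensor, records, cells, variants=variants)
        # with no ambient contamination the correction removes (almost) nothing
        assert report.total_removed <= len(cells)  # at most noise-level
        assert report.rho_median == pytest.approx(0.0, abs=0.01)

    def test_removed_totals_conserved(self):
        tensor, records, truth = self._setup(rho=0.05)
        cells = truth.cells()
        variants = sorted(truth.variant_origin, key=lambda v: v.position)
        result, report = remove_background(tensor, records, cells, variants=variants)
        diff = 0
        for v in variants:
            for c in cells:
                pre = tensor.count(c, v.position, v.alt, "fwd") + tensor.count(c, v.position, v.alt, "rev")
                post = result.corrected.count(c, v.position, v.alt, "fwd") + result.corrected.count(c, v.position, v.alt, "rev")
                diff += pre - post
        assert diff == result.total_removed == report.total_removed

    def test_requires_variants_or_reference(self):
        tensor, records, truth = self._setup(rho=0.0)
        with pytest.raises(ArgumentError):
            remove_background(tensor, records, truth.cells())

    def test_reference_pathway(self):
        tensor, records, truth = self._setup(rho=0.05)
        cells = truth.cells()
        result, report = remove_background(
            tensor, records, cells, reference=truth.reference
        )
        assert report.n_variants >= len(truth.variant_origin)
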