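import math

import numpy as np
import pytest

from cryoclone.counts import StrandBaseCounts, Variant
from cryoclone.errors import ArgumentError
from cryoclone.genotyping import (
    DEFAULT_ARTIFACT_BLOCKLIST,
    HeteroplasmyMatrix,
    VariantMetrics,
    call_candidate_variants,
    compute_heteroplasmy,
    compute_variant_metrics,
    drop_artifact_variants,
    filter_high_confidence,
    pseudobulk_heteroplasmy,
    substitution_spectrum,
    variant_set_overlap,
)

from conftest import random_tensor


def _make_het(af_rows, cov_rows, variants=None, alt=None):
    af = np.asarray(af_rows, dtype=float)
    cov = np.asarray(cov_rows)
    cells = [f"c{i}" for i in range(af.shape[0])]
    if variants is None:
        variants = [Variant(j + 1, "A", "G") for j in range(af.shape[1])]
    kw = {}
    if alt is not None:
        kw = {"alt_fwd": alt[0], "alt_rev": alt[1]}
    return HeteroplasmyMatrix(cells, variants, af, cov, **kw)


class TestComputeHeteroplasmy:
    def test_basic_fraction(self, tiny_tensor, v5):
        het = compute_heteroplasmy(tiny_tensor, [v5], ["cellA", "cellB"])
        assert het.af[0, 0] == pytest.approx(5 / 20)
        assert het.cov[0, 0] == 20
        assert het.af[1, 0] == 0.0
        assert not het.missing[1, 0]

    def test_half(self):
        entries = [
            ("b1", 3, "G", "fwd", 5), ("b1", 3, "G", "rev", 5),
            ("b1", 3, "A", "fwd", 5), ("b1", 3, "A", "rev", 5),
        ]
        t = StrandBaseCounts.from_entries(["b1"], 10, entries)
        het = compute_heteroplasmy(t, [Variant(3, "G", "A")], ["b1"])
        assert het.af[0, 0] == pytest.approx(0.5)

    def test_zero_coverage_missing(self, tiny_tensor, v5):
        het = compute_heteroplasmy(tiny_tensor, [Variant(9, "A", "C")], ["cellA"])
        assert het.missing[0, 0]
        assert het.af[0, 0] == 0.0

    def test_matches_brute_force(self, rng):
        tensor = random_tensor(rng, n_barcodes=10, genome_length=30)
        variants = [Variant(p, "A", "G") for p in (2, 7, 19)]
        het = compute_heteroplasmy(tensor, variants)
        for i, b in enumerate(tensor.barcodes):
            for j, v in enumerate(variants):
                cov = tensor.coverage(b, v.position)
                alt = tensor.count(b, v.position, "G", "fwd") + tensor.count(b, v.position, "G", "rev")
                expect = alt / cov if cov else 0.0
                assert het.af[i, j] == pytest.approx(expect, abs=1e-12)
                assert het.cov[i, j] == cov

    def test_af_bounds_invariant(self, rng):
        tensor = random_tensor(rng, n_barcodes=12, genome_length=40)
        variants = [Variant(p, "C", "T") for p in range(1, 41, 5)]
        het = compute_heteroplasmy(tensor, variants)
        assert np.all(het.af >= 0) and np.all(het.af <= 1)
        assert np.all(het.alt_total <= het.cov)


class TestCallCandidateVariants:
    def test_empty_tensor(self):
        t = StrandBaseCounts(["b1"], 10)
        assert call_candidate_variants(t, "A" * 10) == []

    def test_single_variant(self):
        entries = [("b1", 6, "G", "fwd", 10), ("b1", 6, "A", "fwd", 3)]
        t = StrandBaseCounts.from_entries(["b1"], 10, entries)
        ref = "AAAAAG" + "A" * 4
        assert call_candidate_variants(t, ref) == [Variant(6, "G", "A")]

    def test_n_reference_skipped(self):
        entries = [("b1", 6, "A", "fwd", 3)]
        t = StrandBaseCounts.from_entries(["b1"], 10, entries)
        ref = "AAAAAN" + "A" * 4
        assert call_candidate_variants(t, ref) == []

    def test_length_mismatch(self):
        t = StrandBaseCounts(["b1"], 10)
        with pytest.raises(ArgumentError, match="length"):
            call_candidate_variants(t, "AAA")

    def test_simulator_truth_recovery(self):
        from cryoclone.simulate import simulate_experiment, two_donor_mixing_config

        cfg = two_donor_mixing_config(
            seed=11, n_cells_per_donor=40, n_empty=0, genome_length=400,
            ambient_rho=0.0, seq_error_rate=0.0, depth_mean=30,
        )
        tensor, _, truth = simulate_experiment(cfg)
        called = call_candidate_variants(tensor, truth.reference, truth.cells())
        assert set(called) == set(truth.variant_origin)


class TestVariantMetrics:
    def test_zero_alt_everywhere(self):
        alt = (np.zeros((3, 1), int), np.zeros((3, 1), int))
        het = _make_het(np.zeros((3, 1)), np.full((3, 1), 10), alt=alt)
        (m,) = compute_variant_metrics(het)
        assert m.n_cells_conf_detected == 0
        assert m.log10_vmr is None
        assert m.strand_concordance is None
        assert m.pseudobulk_het_mean == 0.0

    def test_proportional_strand_counts(self):
        fwd = np.array([[2], [4], [6]])
        rev = np.array([[1], [2], [3]])
        cov = np.full((3, 1), 20)
        af = (fwd + rev) / cov
        het = _make_het(af, cov, alt=(fwd, rev))
        (m,) = compute_variant_metrics(het)
        assert m.strand_concordance == pytest.approx(1.0)

    def test_vmr_hand_computed(self):
        # af [0, 0, 1, 1]: mean .5, population variance .25, VMR .5
        fwd = np.array([[0], [0], [5], [5]])
        rev = np.array([[0], [0], [5], [5]])
        cov = np.full((4, 1), 10)
        af = np.array([[0.0], [0.0], [1.0], [1.0]])
        het = _make_het(af, cov, alt=(fwd, rev))
        (m,) = compute_variant_metrics(het)
        assert m.log10_vmr == pytest.approx(math.log10(0.5), abs=1e-10)
        assert m.pseudobulk_het_mean == pytest.approx(0.5)
        assert m.pseudobulk_het_aggregate == pytest.approx(0.5)
        assert m.mean_coverage == pytest.approx(10.0)
        assert m.n_cells_conf_detected == 2
        assert m.n_cells_over_threshold == 2

    def test_conf_detection_rules(self):
        # one alt read on a single strand is not confident
        fwd = np.array([[2], [1], [0]])
        rev = np.array([[0], [1], [0]])
        cov = np.full((3, 1), 10)
        af = (fwd + rev) / cov
        het = _make_het(af, cov, alt=(fwd, rev))
        (m,) = compute_variant_metrics(het)
        assert m.n_cells_conf_detected == 1  # only the (1,1) cell


class TestHighConfidenceFilter:
    def _metrics(self, n, sc, vmr, cov):
        return VariantMetrics(Variant(1, "A", "G"), n, sc, cov, vmr, 0.1, 0.1, 0)

    def test_boundary_semantics(self):
        assert filter_high_confidence([self._metrics(5, 0.66, -1.9, 5.0)])
        assert not filter_high_confidence([self._metrics(5, 0.65, -1.9, 5.0)])
        assert not filter_high_confidence([self._metrics(4, 0.9, 0.0, 50.0)])
        assert not filter_high_confidence([self._metrics(5, 0.9, -2.0, 5.0)])
        assert filter_high_confidence([self._metrics(5, 0.9, -1.999, 5.0)])
        assert not filter_high_confidence([self._metrics(5, 0.9, 0.0, 4.999)])

    def test_undefined_metric_fails(self):
        assert not filter_high_confidence([self._metrics(5, None, 0.0, 10.0)])
        assert not filter_high_confidence([self._metrics(5, 0.9, None, 10.0)])

    def test_matches_brute_force_predicate(self, rng):
        ms = [
            self._metrics(
                int(rng.integers(0, 10)),
                None if rng.random() < 0.1 else float(rng.uniform(0, 1)),
                None if rng.random() < 0.1 else float(rng.uniform(-4, 1)),
                float(rng.uniform(0, 20)),
            )
            for _ in range(200)
        ]
        got = filter_high_confidence(ms)
        expected = [
            m.variant
            for m in ms
            if m.n_cells_conf_detected >= 5
            and m.strand_concordance is not None and m.strand_concordance > 0.65
            and m.log10_vmr is not None and m.log10_vmr > -2
            and m.mean_coverage >= 5
        ]
        assert got == expected


class TestArtifactBlocklist:
    def test_default_blocklist_content(self):
        labels = {v.label for v in DEFAULT_ARTIFACT_BLOCKLIST}
        assert labels == {
            "mt.301A>C", "mt.302A>C", "mt.309C>T", "mt.310T>C",
            "mt.316G>C", "mt.3109T>C", "mt.189A>G",
        }

    def test_removes_blocklisted(self):
        vs = [Variant(301, "A", "C"), Variant(1206, "G", "A")]
        assert drop_artifact_variants(vs) == [Variant(1206, "G", "A")]

    def test_disjoint_unchanged(self):
        vs = [Variant(1206, "G", "A"), Variant(953, "T", "C")]
        assert drop_artifact_variants(vs) == vs

    def test_mixed_fixture_size(self, rng):
        extra = [Variant(int(p), "A", "G") for p in rng.choice(
            [x for x in range(400, 3000, 7)], size=7, replace=False)]
        mixed = list(DEFAULT_ARTIFACT_BLOCKLIST[:3]) + extra
        out = drop_artifact_variants(mixed)
        assert len(out) == len(mixed) - 3
        assert set(out) == set(extra)


class TestPseudobulk:
    def test_single_cell(self):
        het = _make_het([[0.4]], [[10]])
        groups = {"c0": "g"}
        assert pseudobulk_heteroplasmy(het, groups, "mean").loc["mt.1A>G", "g"] == pytest.approx(0.4)
        assert pseudobulk_heteroplasmy(het, groups, "aggregate").loc["mt.1A>G", "g"] == pytest.approx(0.4)

    def test_equal_coverage_modes_coincide(self):
        het = _make_het([[0.0], [0.5]], [[10], [10]])
        groups = {"c0": "g", "c1": "g"}
        for mode in ("mean", "aggregate"):
            assert pseudobulk_heteroplasmy(het, groups, mode).loc["mt.1A>G", "g"] == pytest.approx(0.25)

    def test_unequal_coverage_modes_diverge(self):
        het = _make_het([[0.0], [0.5]], [[100], [10]])
        groups = {"c0": "g", "c1": "g"}
        assert pseudobulk_heteroplasmy(het, groups, "mean").loc["mt.1A>G", "g"] == pytest.approx(0.25)
        assert pseudobulk_heteroplasmy(het, groups, "aggregate").loc["mt.1A>G", "g"] == pytest.approx(5 / 110)

    def test_uncovered_group_is_nan(self):
        het = _make_het([[0.0]], [[0]])
        out = pseudobulk_heteroplasmy(het, {"c0": "g"}, "mean")
        assert np.isnan(out.loc["mt.1A>G", "g"])

    def test_unlabeled_cell_rejected(self):
        het = _make_het([[0.4]], [[10]])
        with pytest.raises(ArgumentError):
            pseudobulk_heteroplasmy(het, {}, "mean")

    def test_random_fixture_matches_oracle(self, rng):
        n, m = 30, 4
        cov = rng.integers(0, 20, size=(n, m))
        alt = np.array([[rng.integers(0, c + 1) for c in row] for row in cov])
        af = np.where(cov > 0, alt / np.maximum(cov, 1), 0.0)
        cells = [f"c{i}" for i in range(n)]
        variants = [Variant(j + 1, "C", "T") for j in range(m)]
        half = np.array([[rng.integers(0, a + 1) for a in row] for row in alt])
        het = HeteroplasmyMatrix(cells, variants, af, cov, alt_fwd=half, alt_rev=alt - half)
        groups = {c: f"g{i % 3}" for i, c in enumerate(cells)}
        table = pseudobulk_heteroplasmy(het, groups, "aggregate")
        for g in ("g0", "g1", "g2"):
            rows = [i for i, c in enumerate(cells) if groups[c] == g]
            for j, v in enumerate(variants):
                tot_alt = sum(alt[i, j] for i in rows)
                tot_cov = sum(cov[i, j] for i in rows)
                if tot_cov:
                    assert table.loc[v.label, g] == pytest.approx(tot_alt / tot_cov, abs=1e-12)


class TestSubstitutionSpectrum:
    def test_all_ct(self):
        spec = substitution_spectrum([Variant(100, "C", "T"), Variant(200, "C", "T")])
        assert spec.loc["C>T", "count"] == 2
        assert spec.loc["C>T", "proportion"] == pytest.approx(1.0)

    def test_empty(self):
        spec = substitution_spectrum([])
        assert (spec["count"] == 0).all()
        assert (spec["proportion"] == 0).all()

    def test_collapse_maps_purines(self):
        spec = substitution_spectrum([Variant(5, "G", "A")])
        assert spec.loc["G>A", "collapsed_class"] == "C>T"

    def test_random_tally(self, rng):
        import itertools

        classes = [(r, a) for r in "ACGT" for a in "ACGT" if r != a]
        vs = []
        for i in range(50):
            r, a = classes[int(rng.integers(0, 12))]
            vs.append(Variant(i + 1, r, a))
        spec = substitution_spectrum(vs)
        assert int(spec["count"].sum()) == 50
        assert spec["proportion"].sum() == pytest.approx(1.0)
        from collections import Counter

        tally = Counter(f"{v.ref}>{v.alt}" for v in vs)
        for cls, cnt in tally.items():
            assert spec.loc[cls, "count"] == cnt


class TestVariantSetOverlap:
    def test_identical_sets(self):
        vs = {Variant(1, "A", "G"), Variant(2, "C", "T")}
        member, combos = variant_set_overlap({"A": vs, "B": vs})
        assert combos == {frozenset({"A", "B"}): 2}
        assert member.all().all()

    def test_disjoint(self):
        _, combos = variant_set_overlap(
            {"A": {Variant(1, "A", "G")}, "B": {Variant(2, "C", "T")}}
        )
        assert frozenset({"A", "B"}) not in combos

    def test_four_group_partition(self, rng):
        groups = {}
        pool = [Variant(p, "A", "G") for p in range(1, 60)]
        for g in "ABCD":
            groups[g] = set(
                pool[i] for i in rng.choice(len(pool), size=20, replace=False)
            )
        member, combos = variant_set_overlap(groups)
        union = set().union(*groups.values())
        assert sum(combos.values()) == len(union) == len(member)
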