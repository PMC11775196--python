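import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import bh_stepup
from nfiomics.hci_filtering import FilterConfig, primary_bfdr_filter
from nfiomics.interaction_scoring import ScoredInteraction
from nfiomics.interactome_analysis import (
    differential_isoform,
    dotplot_table,
    localization_profile,
    replicate_correlation,
    stability_scores,
    timepoint_shift,
    venn,
)
from nfiomics.io_formats import RunRecord, RunTable
from nfiomics.synthetic_data import SimulationConfig, simulate_isoform_pair


class TestVenn:
    def test_disjoint_sets(self):
        part = venn({"A": {"a"}, "B": {"b"}})
        assert part.count("A") == 1 and part.count("B") == 1 and part.count("A", "B") == 0

    def test_identical_sets_only_full_intersection(self):
        part = venn({"A": {"x", "y"}, "B": {"x", "y"}})
        assert part.count("A", "B") == 2
        assert part.count("A") == 0 and part.count("B") == 0

    def test_matches_per_element_classification(self):
        rng = np.random.default_rng(0)
        universe = [f"g{i}" for i in range(100)]
        families = {
            label: set(rng.choice(universe, size=50, replace=False)) for label in "ABCD"
        }
        part = venn(families)
        for element in universe:
            membership = frozenset(l for l in families if element in families[l])
            if membership:
                assert element in part.regions[membership]
        assert part.union_size == len(set().union(*families.values()))

    @given(
        st.dictionaries(
            st.sampled_from("ABCD"),
            st.sets(st.integers(0, 30)),
            min_size=1,
            max_size=4,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_regions_partition_the_union(self, families):
        part = venn(families)
        union = set().union(*families.values())
        assert part.union_size == len(union)
        seen = set()
        for members in part.regions.values():
            assert not (seen & members)
            seen |= members
        assert seen == union


def _table_two_runs(vec_a, vec_b):
    runs = [
        RunRecord("a", "X", "BIOID", 3.0, "HEK", 1),
        RunRecord("b", "X", "BIOID", 3.0, "HEK", 2),
    ]
    counts = {}
    for i, v in enumerate(vec_a):
        if v:
            counts[("a", f"P{i}")] = v
    for i, v in enumerate(vec_b):
        if v:
            counts[("b", f"P{i}")] = v
    return RunTable(runs=runs, counts=counts)


class TestReplicateCorrelation:
    def test_identical_runs_perfectly_correlated(self):
        t = _table_two_runs([5, 3, 8], [5, 3, 8])
        assert replicate_correlation(t, "a", "b") == pytest.approx(1.0)

    def test_anti_ordered_runs(self):
        t = _table_two_runs([1, 2, 3], [3, 2, 1])
        assert replicate_correlation(t, "a", "b") == pytest.approx(-1.0)

    def test_matches_direct_covariance_formula(self):
        rng = np.random.default_rng(3)
        a, b = rng.integers(1, 40, 20), rng.integers(1, 40, 20)
        t = _table_two_runs(list(a), list(b))
        af, bf = a.astype(float), b.astype(float)
        expected = ((af - af.mean()) * (bf - bf.mean())).sum() / (
            np.sqrt(((af - af.mean()) ** 2).sum()) * np.sqrt(((bf - bf.mean()) ** 2).sum())
        )
        assert replicate_correlation(t, "a", "b") == pytest.approx(expected)

    def test_too_few_preys_rejected(self):
        t = _table_two_runs([5], [3])
        with pytest.raises(ValueError):
            replicate_correlation(t, "a", "b")


class TestDifferentialIsoform:
    def _table(self, fl, sh):
        counts = {}
        runs = [RunRecord(f"fl{i}", "FL", "BIOID", 3.0, "HEK", i + 1) for i in range(len(fl))]
        runs += [RunRecord(f"sh{i}", "SH", "BIOID", 3.0, "HEK", i + 1) for i in range(len(sh))]
        for i, row in enumerate(fl):
            for prey, c in row.items():
                counts[(f"fl{i}", prey)] = c
        for i, row in enumerate(sh):
            for prey, c in row.items():
                counts[(f"sh{i}", prey)] = c
        return RunTable(runs=runs, counts=counts)

    def test_identical_matrices_all_ns(self):
        rows = [{"P1": 5, "P2": 9}, {"P1": 5, "P2": 9}]
        res = differential_isoform(self._table(rows, rows), "FL", "SH")
        assert all(r.klass == "ns" and r.log2fc == 0.0 for r in res)

    def test_short_only_prey_classified_up(self):
        fl = [{"P0": 10}, {"P0": 10}, {"P0": 10}]
        sh = [{"P0": 10, "PX": 60}, {"P0": 10, "PX": 55}, {"P0": 10, "PX": 70}]
        res = {r.prey_id: r for r in differential_isoform(self._table(fl, sh), "FL", "SH")}
        assert res["PX"].klass == "up"
        assert res["P0"].klass == "ns"

    def test_antisymmetric_under_bait_swap(self):
        table, _ = simulate_isoform_pair(SimulationConfig(seed=6, n_preys=40), 5, 5, 2.0, seed=6)
        fwd = {r.prey_id: r for r in differential_isoform(table, "ISO_FL", "ISO_SHORT")}
        rev = {r.prey_id: r for r in differential_isoform(table, "ISO_SHORT", "ISO_FL")}
        for prey, r in fwd.items():
            assert rev[prey].log2fc == pytest.approx(-r.log2fc)
            assert {"up": "down", "down": "up", "ns": "ns"}[r.klass] == rev[prey].klass

    def test_single_replicate_rejected(self):
        fl = [{"P1": 5}]
        sh = [{"P1": 5}, {"P1": 6}]
        with pytest.raises(ValueError):
            differential_isoform(self._table(fl, sh), "FL", "SH")

    def test_recovers_planted_differential_preys(self):
        hit = total = 0
        for seed in range(5):
            cfg = SimulationConfig(signal_mean=40.0, seed=seed)
            table, truth = simulate_isoform_pair(cfg, 20, 20, 3.0, seed=seed)
            res = differential_isoform(table, "ISO_FL", "ISO_SHORT")
            up = {r.prey_id for r in res if r.klass == "up"}
            down = {r.prey_id for r in res if r.klass == "down"}
            hit += len(up & truth.diff_up_preys) + len(down & truth.diff_down_preys)
            total += len(truth.diff_up_preys) + len(truth.diff_down_preys)
        assert hit / total >= 0.9


class TestBenjaminiHochberg:
    @pytest.mark.parametrize("seed", range(5))
    def test_multipletests_matches_stepup_oracle(self, seed):
        # the BH adjustment used throughout must equal the textbook step-up
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(seed)
        p = rng.random(int(rng.integers(1, 200)))
        _, adj, _, _ = multipletests(p, method="fdr_bh")
        assert list(adj) == pytest.approx(bh_stepup(list(p)))


class TestLocalizationProfile:
    def test_single_compartment(self):
        prof = localization_profile(["P1", "P2"], {"P1": [("nucleus", 3.0)], "P2": [("nucleus", 1.0)]})
        assert prof.scores == {"nucleus": 1.0}

    def test_empty_hci_set(self):
        assert localization_profile([], {"P1": [("nucleus", 1.0)]}).scores == {}

    def test_max_normalization(self):
        prof = localization_profile(
            ["P1", "P2"],
            {"P1": [("nucleus", 8.0)], "P2": [("cytosol", 2.0)]},
        )
        assert prof.scores == {"nucleus": 1.0, "cytosol": 0.25}


class TestStabilityScores:
    def _table(self, apms_counts, bioid_counts, bait_apms=10, bait_bioid=20):
        runs = [
            RunRecord("ap1", "X", "APMS", 0.0, "HEK", 1),
            RunRecord("bi1", "X", "BIOID", 3.0, "HEK", 1),
        ]
        counts = {("ap1", "X"): bait_apms, ("bi1", "X"): bait_bioid}
        for prey, c in apms_counts.items():
            counts[("ap1", prey)] = c
        for prey, c in bioid_counts.items():
            counts[("bi1", prey)] = c
        return RunTable(runs=runs, counts=counts)

    def test_equal_normalized_abundance_is_half(self):
        t = self._table({"P1": 5}, {"P1": 10})  # 5/10 == 10/20
        (s,) = stability_scores(t, "X")
        assert s.s == pytest.approx(0.5) and not s.one_sided

    def test_bioid_only_prey_flagged_zero(self):
        t = self._table({}, {"P1": 10})
        (s,) = stability_scores(t, "X")
        assert s.s == 0.0 and s.one_sided

    def test_invariant_under_joint_run_rescaling(self):
        rng = np.random.default_rng(1)
        preys = {f"P{i}": int(rng.integers(1, 30)) for i in range(10)}
        bio = {f"P{i}": int(rng.integers(1, 30)) for i in range(10)}
        base = stability_scores(self._table(preys, bio), "X")
        scaled = stability_scores(
            self._table({k: v * 3 for k, v in preys.items()}, bio, bait_apms=30), "X"
        )
        for s1, s2 in zip(base, scaled):
            assert s2.s == pytest.approx(s1.s)

    def test_missing_assay_rejected(self):
        runs = [RunRecord("bi1", "X", "BIOID", 3.0, "HEK", 1)]
        t = RunTable(runs=runs, counts={("bi1", "X"): 5})
        with pytest.raises(ValueError):
            stability_scores(t, "X")


class TestTimepointShift:
    def test_set_algebra(self):
        shift = timepoint_shift({"B": {"p1", "p2"}}, {"B": {"p2", "p3"}})
        assert shift["B"] == {"lost": {"p1"}, "kept": {"p2"}, "gained": {"p3"}}

    def test_missing_bait_treated_as_empty(self):
        shift = timepoint_shift({"B": {"p1"}}, {})
        assert shift["B"]["lost"] == {"p1"} and shift["B"]["gained"] == set()

    def test_identical_lists_all_kept(self):
        shift = timepoint_shift({"B": {"p"}}, {"B": {"p"}})
        assert shift["B"]["lost"] == set() == shift["B"]["gained"]


class TestDotplotTable:
    def _hcis(self):
        cfg = FilterConfig()
        out = {}
        for bait, spec in [("NFIA", 10.0), ("NFIB", 5.0)]:
            si = ScoredInteraction(bait, "SMARCA4", "BIOID", 3.0, spec, [1.0], 1.0, 0.0)
            out[(bait, "BIOID", 3.0)] = primary_bfdr_filter([si], cfg)
        return out

    def test_relative_abundance_max_normalized(self):
        df = dotplot_table(self._hcis())
        by_bait = df.set_index("bait_id")["relative_abundance"]
        assert by_bait["NFIA"] == pytest.approx(1.0)
        assert by_bait["NFIB"] == pytest.approx(0.5)
        assert ((df["relative_abundance"] > 0) & (df["relative_abundance"] <= 1)).all()

    def test_complex_restriction(self):
        df = dotplot_table(self._hcis(), {"SWI_SNF": {"SMARCA4"}, "MED": {"MED1"}})
        assert set(df["complex"]) == {"SWI_SNF"}
        empty = dotplot_table(self._hcis(), {"MED": {"MED1"}})
        assert empty.empty
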