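"""Trait aggregation: binning, core genera, profiles, trajectories.

The profile oracle below recomputes every trait field by explicit
enumeration with plain Python loops, independently of the implementation.
"""

import itertools
import math

import numpy as np
import pytest

from rrntraits import (
    RrnLookup,
    assign_rrn,
    bin_rrn,
    core_genera,
    genera_ratio,
    relative_abundance,
    rrn_class_abundance,
    trait_profile,
    trait_profiles,
    trajectory,
)
from rrntraits.rrn import RrnAssignment
from rrntraits.traits import classify_rrn

from conftest import make_table


def brute_force_profile(props, rrn, genus):
    """Oracle: explicit-enumeration recomputation of all trait fields.

    props/rrn/genus are parallel lists over OTUs of one sample; props are
    already renormalized proportions over assigned OTUs.
    """
    lcn = sum(p for p, r in zip(props, rrn) if r in (1, 2, 3))
    hcn = sum(p for p, r in zip(props, rrn) if r in range(4, 16))
    ratio = hcn / lcn if lcn > 0 else math.nan
    total = sum(props)
    cwm = sum(p * r for p, r in zip(props, rrn)) / total
    present = [(p, r, g) for p, r, g in zip(props, rrn, genus) if p > 0]
    mean_presence = sum(r for _, r, _ in present) / len(present)
    g_lcn = {g for p, r, g in present if r <= 3}
    g_hcn = {g for p, r, g in present if r >= 4}
    return lcn, hcn, ratio, cwm, mean_presence, len(g_lcn), len(g_hcn)


def profile_from_lists(props, rrn, genus):
    otus = [f"o{i}" for i in range(len(props))]
    rel = relative_abundance(make_table([[int(round(p * 1000))] for p in props], otu_ids=otus))
    assignment = RrnAssignment(dict(zip(otus, rrn)), frozenset())
    taxonomy = dict(zip(otus, genus))
    return trait_profile(rel, assignment, taxonomy, "s1")


class TestBinning:
    @pytest.mark.parametrize("copies,expected", [
        (1, "LCN"), (3, "LCN"), (4, "HCN"), (15, "HCN"),
    ])
    def test_bin_boundaries(self, copies, expected):
        assert classify_rrn(copies) == expected

    def test_partition_exhaustive(self):
        assignment = RrnAssignment({f"o{c}": c for c in range(1, 16)}, frozenset())
        bins = bin_rrn(assignment)
        assert all(bins[f"o{c}"] in ("LCN", "HCN") for c in range(1, 16))
        assert sum(bins[f"o{c}"] == "LCN" for c in range(1, 16)) == 3

    def test_unassigned_excluded(self):
        assignment = RrnAssignment({"a": 2}, frozenset({"b"}))
        assert set(bin_rrn(assignment)) == {"a"}


class TestProfileOracle:
    def test_spec_worked_example(self):
        prof = profile_from_lists([0.5, 0.2, 0.3], [2, 3, 5], ["ga", "gb", "gc"])
        assert prof.lcn_abund == pytest.approx(0.7)
        assert prof.hcn_abund == pytest.approx(0.3)
        assert prof.ratio_hcn_lcn == pytest.approx(0.3 / 0.7)
        assert prof.cwm_rrn_abundance == pytest.approx(3.1)

    def test_single_bin_sample(self):
        prof = profile_from_lists([0.6, 0.4], [2, 2], ["ga", "gb"])
        assert prof.ratio_hcn_lcn == 0.0
        assert prof.cwm_rrn_abundance == pytest.approx(2.0)
        assert prof.mean_rrn_presence == pytest.approx(2.0)

    def test_symmetric_presence_mean(self):
        prof = profile_from_lists([1 / 3] * 3, [1, 2, 3], ["a", "b", "c"])
        assert prof.mean_rrn_presence == pytest.approx(2.0)

    def test_two_otu_tables_exhaustive(self):
        # every 2-OTU table over the full rrn x weight grid
        rrn_choices = [1, 2, 3, 4, 9, 15]
        weight_grid = [0, 1, 2, 5]
        for rrn in itertools.product(rrn_choices, repeat=2):
            for w in itertools.product(weight_grid, repeat=2):
                if sum(w) == 0:
                    continue
                self._check_against_oracle(list(rrn), w, ["g0", "g1"])

    def test_sampled_grid_up_to_six_otus(self):
        # larger tables: a seeded subsample of the rrn x weight product
        rng = np.random.default_rng(20170925)
        rrn_choices = [1, 3, 4, 9, 15]
        weight_grid = [0, 1, 2, 5]
        for n_otus in (3, 4, 6):
            genus = [f"g{i % 2}" for i in range(n_otus)]
            for _ in range(100):
                rrn = [int(r) for r in rng.choice(rrn_choices, size=n_otus)]
                w = tuple(int(x) for x in rng.choice(weight_grid, size=n_otus))
                if sum(w) == 0:
                    continue
                self._check_against_oracle(rrn, w, genus)

    def _check_against_oracle(self, rrn, w, genus):
        props = [x / sum(w) for x in w]
        exp = brute_force_profile(props, rrn, genus)
        otus = [f"o{i}" for i in range(len(w))]
        rel = relative_abundance(make_table([[x] for x in w], otu_ids=otus))
        assignment = RrnAssignment(dict(zip(otus, rrn)), frozenset())
        prof = trait_profile(rel, assignment, dict(zip(otus, genus)), "s1")
        assert prof.lcn_abund == pytest.approx(exp[0], abs=1e-12)
        assert prof.hcn_abund == pytest.approx(exp[1], abs=1e-12)
        if math.isnan(exp[2]):
            assert math.isnan(prof.ratio_hcn_lcn)
        else:
            assert prof.ratio_hcn_lcn == pytest.approx(exp[2], abs=1e-12)
        assert prof.cwm_rrn_abundance == pytest.approx(exp[3], abs=1e-12)
        assert prof.mean_rrn_presence == pytest.approx(exp[4], abs=1e-12)
        assert (prof.n_genera_lcn, prof.n_genera_hcn) == (exp[5], exp[6])
        assert prof.lcn_abund + prof.hcn_abund == pytest.approx(1.0, abs=1e-9)

    def test_zero_assigned_abundance_flagged(self):
        rel = relative_abundance(make_table([[0, 5], [0, 5]], otu_ids=["a", "b"]))
        assignment = RrnAssignment({"a": 2, "b": 5}, frozenset())
        prof = trait_profile(rel, assignment, {"a": "x", "b": "y"}, "s1")
        assert not prof.defined
        assert math.isnan(prof.ratio_hcn_lcn)

    def test_cwm_invariant_to_splitting_same_genus(self):
        whole = profile_from_lists([0.4, 0.6], [2, 5], ["ga", "gb"])
        split = profile_from_lists([0.2, 0.2, 0.6], [2, 2, 5], ["ga", "ga", "gb"])
        assert split.cwm_rrn_abundance == pytest.approx(whole.cwm_rrn_abundance)
        assert split.ratio_hcn_lcn == pytest.approx(whole.ratio_hcn_lcn)
        assert split.n_genera_lcn == whole.n_genera_lcn

    def test_lcn_to_hcn_transfer_increases_ratio(self):
        base = profile_from_lists([0.5, 0.5], [2, 5], ["a", "b"])
        shifted = profile_from_lists([0.4, 0.6], [2, 5], ["a", "b"])
        assert shifted.ratio_hcn_lcn > base.ratio_hcn_lcn


class TestCoreGenera:
    def _table_for(self, genera):
        otus = [f"{g}_o" for g in genera]
        t = make_table([[1]] * len(otus), otu_ids=otus)
        return t, {o: g for o, g in zip(otus, genera)}

    def test_intersection(self):
        tables = [self._table_for(g) for g in (["A", "B", "C"], ["B", "C", "D"], ["B", "C"])]
        core, fractions = core_genera(tables)
        assert core == {"b", "c"}
        assert fractions[2] == pytest.approx(1.0)
        assert fractions[0] == pytest.approx(2 / 3)

    def test_single_table_identity(self):
        core, _ = core_genera([self._table_for(["A", "B"])])
        assert core == {"a", "b"}

    def test_disjoint_warns_empty(self):
        tables = [self._table_for(["A"]), self._table_for(["B"])]
        with pytest.warns(UserWarning, match="empty"):
            core, _ = core_genera(tables)
        assert core == set()

    def test_zero_count_is_absent(self):
        t = make_table([[0], [2]], otu_ids=["x_o", "y_o"])
        tax = {"x_o": "X", "y_o": "Y"}
        core, _ = core_genera([(t, tax)])
        assert core == {"y"}


class TestGeneraRatio:
    def test_study_oligotrophic_counts(self):
        # replicate-mean genus counts per bin give the printed two-decimal ratio
        assert round(genera_ratio(34.3, 97.4), 2) == 0.35

    def test_identity_and_zero(self):
        assert genera_ratio(1, 1) == 1.0
        assert genera_ratio(0, 10) == 0.0
        assert math.isnan(genera_ratio(10, 0))


class TestTrajectory:
    def _profiles(self, rows):
        import pandas as pd
        return pd.DataFrame(rows)

    def test_replicate_mean_sd_phase(self):
        prof = self._profiles([
            {"ratio_hcn_lcn": 0.2, "time_days": 10, "replicate": "a"},
            {"ratio_hcn_lcn": 0.3, "time_days": 10, "replicate": "b"},
            {"ratio_hcn_lcn": 0.4, "time_days": 10, "replicate": "c"},
        ])
        traj = trajectory(prof)
        assert traj.loc[0, "mean"] == pytest.approx(0.3)
        assert traj.loc[0, "sd"] == pytest.approx(0.1)
        assert traj.loc[0, "phase"] == "initial"

    def test_single_replicate_sd_zero(self):
        prof = self._profiles([{"ratio_hcn_lcn": 0.5, "time_days": 30, "replicate": "a"}])
        traj = trajectory(prof)
        assert traj.loc[0, "sd"] == 0.0
        assert traj.loc[0, "phase"] == "late"

    def test_day25_is_initial_inclusive(self):
        prof = self._profiles([{"ratio_hcn_lcn": 0.5, "time_days": 25, "replicate": "a"}])
        assert trajectory(prof).loc[0, "phase"] == "initial"

    def test_undefined_value_reduces_n_with_warning(self):
        prof = self._profiles([
            {"ratio_hcn_lcn": 0.2, "time_days": 5, "replicate": "a"},
            {"ratio_hcn_lcn": math.nan, "time_days": 5, "replicate": "b"},
        ])
        with pytest.warns(UserWarning, match="reduced n"):
            traj = trajectory(prof)
        assert traj.loc[0, "n"] == 1


class TestClassAbundance:
    def test_per_class_sums(self):
        t = make_table([[2], [3], [5]], otu_ids=["a", "b", "c"])
        rel = relative_abundance(t)
        assignment = RrnAssignment({"a": 2, "b": 2, "c": 9}, frozenset())
        out = rrn_class_abundance(rel, assignment)
        assert out.loc[2, "s1"] == pytest.approx(0.5)
        assert out.loc[9, "s1"] == pytest.approx(0.5)
        assert out["s1"].sum() == pytest.approx(1.0)


class TestEndToEndProfiles:
    def test_profiles_with_core_and_lookup(self, simple_lookup):
        t = make_table([[10, 5], [20, 5], [0, 10]], otu_ids=["a", "b", "c"],
                       meta=[{"sample_id": "s1", "time_days": 1, "replicate": "r1",
                              "group": "x"},
                             {"sample_id": "s2", "time_days": 2, "replicate": "r1",
                              "group": "x"}])
        tax = {"a": "sphingomonas", "b": "flavobacterium", "c": "unknown_genus"}
        prof = trait_profiles(t, tax, simple_lookup)
        # c is unassigned -> renormalized over a and b only
        assert prof.loc["s1", "lcn_abund"] == pytest.approx(10 / 30)
        assert prof.loc["s1", "hcn_abund"] == pytest.approx(20 / 30)
        assert prof.loc["s2", "lcn_abund"] == pytest.approx(0.5)
        assert prof.loc["s1", "time_days"] == 1
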