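"""Transition statistics, zigzag calling, protein presence calls, clustering."""

import numpy as np
import pandas as pd
import pytest
from oracles import bh_bruteforce

from cycleage import (
    ProteomeConfig,
    TimecourseConfig,
    TimecourseMatrix,
    bh_adjust,
    call_cyclic_genes,
    call_cyclic_proteins,
    cluster_timepoints,
    differential_proteins,
    gen_proteome,
    gen_timecourse,
    transition_stats,
)
from cycleage.cyclic_detect import ProteomeTable
from cycleage.exceptions import InputError, ParameterError


def _matrix(rows: dict[str, list[list[float]]], timepoints=(3, 11, 14, 19)) -> TimecourseMatrix:
    n_rep = len(next(iter(rows.values()))[0])
    cols = pd.MultiIndex.from_product([timepoints, range(1, n_rep + 1)],
                                      names=["timepoint", "replicate"])
    data = {g: np.concatenate(v) for g, v in rows.items()}
    return TimecourseMatrix(values=pd.DataFrame.from_dict(data, orient="index", columns=cols))


class TestTransitionStats:
    def test_identical_replicates_give_zero_lfc_p_one(self):
        tc = _matrix({"g1": [[1.0, 2.0, 3.0]] * 4})
        st = transition_stats(tc)
        assert np.allclose(st.lfc.loc["g1"], 0.0)
        assert np.allclose(st.p.loc["g1"], 1.0)

    def test_noise_free_means_give_exact_lfc(self):
        tc = _matrix({"g1": [[2.0, 2.0], [5.0, 5.0], [2.0, 2.0], [5.0, 5.0]]})
        st = transition_stats(tc)
        assert np.allclose(st.lfc.loc["g1"], [3.0, -3.0, 3.0])

    def test_welch_closed_form_example(self):
        tc = _matrix({"g1": [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [1, 2, 3], [4, 5, 6]]})
        st = transition_stats(tc)
        # Welch on [1,2,3] vs [4,5,6]: t = 3/sqrt(2/3), df = 4
        from scipy import stats as ss

        t = 3.0 / np.sqrt(2.0 / 3.0)
        expected_p = 2 * ss.t.sf(t, df=4)
        assert t == pytest.approx(3.674, abs=5e-4)
        assert st.p.loc["g1"].iloc[0] == pytest.approx(expected_p, rel=1e-12)
        assert expected_p == pytest.approx(0.0214, abs=5e-4)

    def test_single_replicate_rejected(self):
        cols = pd.MultiIndex.from_product([(3, 11, 14, 19), [1]])
        tc = TimecourseMatrix(values=pd.DataFrame([[1.0, 2, 3, 4]], index=["g"], columns=cols))
        with pytest.raises(InputError, match="<2 replicates"):
            transition_stats(tc)


class TestBH:
    def test_hand_step_up_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_degenerate_inputs(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            bh_adjust([0.5, 1.5])

    @pytest.mark.parametrize("m", [1, 2, 3, 5, 8])
    def test_matches_bruteforce_definition(self, m, rng):
        for _ in range(40):
            p = rng.random(m)
            np.testing.assert_allclose(bh_adjust(p), bh_bruteforce(p), atol=1e-12)


class TestCallCyclicGenes:
    def test_recovers_planted_noise_free(self, noisefree_timecourse):
        tc, truth = noisefree_timecourse
        calls = call_cyclic_genes(transition_stats(tc), tau=1.0, q_max=0.05)
        called = set(calls.genes)
        planted = set(truth.index[truth.pattern.isin(["udu", "dud"])])
        assert called == planted
        ori = calls.calls["orientation"]
        assert all(ori[g] == truth.loc[g, "pattern"].upper() for g in called)

    def test_monotone_and_flat_never_called(self):
        tc = _matrix({
            "mono": [[0.0, 0.1], [2.0, 2.1], [4.0, 4.1], [6.0, 6.1]],
            "flat": [[1.0, 1.1], [1.0, 1.1], [1.0, 1.1], [1.0, 1.1]],
        })
        st = transition_stats(tc)
        for tau in (0.0, 0.5, 1.0):
            assert len(call_cyclic_genes(st, tau=tau, q_max=1.0)) == 0

    def test_threshold_monotonicity(self, small_timecourse):
        tc, _ = small_timecourse
        st = transition_stats(tc)
        base = set(call_cyclic_genes(st, tau=0.0, q_max=1.0).genes)
        for tau, qmax in [(0.5, 1.0), (1.0, 0.5), (1.5, 0.05)]:
            sub = set(call_cyclic_genes(st, tau=tau, q_max=qmax).genes)
            assert sub <= base
            base_inner = set(call_cyclic_genes(st, tau=tau, q_max=qmax).genes)
            assert base_inner == sub

    def test_negation_swaps_orientations(self, small_timecourse):
        tc, _ = small_timecourse
        neg = TimecourseMatrix(values=-tc.values, genotype=tc.genotype)
        a = call_cyclic_genes(transition_stats(tc), tau=1.0, q_max=0.05).calls
        b = call_cyclic_genes(transition_stats(neg), tau=1.0, q_max=0.05).calls
        assert set(a.index) == set(b.index)
        swapped = a["orientation"].map({"UDU": "DUD", "DUD": "UDU"})
        assert (b.loc[a.index, "orientation"] == swapped).all()

    def test_parameter_validation(self, small_timecourse):
        st = transition_stats(small_timecourse[0])
        with pytest.raises(ParameterError):
            call_cyclic_genes(st, tau=-1)
        with pytest.raises(ParameterError):
            call_cyclic_genes(st, q_max=0.0)

    def test_orientation_subset_restricts_calls(self, noisefree_timecourse):
        tc, truth = noisefree_timecourse
        st = transition_stats(tc)
        only_udu = call_cyclic_genes(st, orientations=("UDU",))
        assert set(only_udu.genes) == set(truth.index[truth.pattern == "udu"])


class TestCallCyclicProteins:
    def test_recovers_planted_set(self, clean_proteome):
        pt, truth = clean_proteome
        assert set(call_cyclic_proteins(pt, "nzb")) == set(truth.index[truth.cyclic])

    def _table(self, presence: dict[tuple[str, int], bool]) -> ProteomeTable:
        cols = pd.MultiIndex.from_product(
            [["c57", "nzb"], [3, 11, 14, 19], [1, 2, 3]],
            names=["genotype", "timepoint", "replicate"],
        )
        vals = [1000.0 if presence.get((gt, tp), False) else np.nan for gt, tp, _ in cols]
        return ProteomeTable(values=pd.DataFrame([vals], index=["p"], columns=cols))

    def test_detected_everywhere_not_called(self):
        pt = self._table({(gt, tp): True for gt in ("c57", "nzb") for tp in (3, 11, 14, 19)})
        assert call_cyclic_proteins(pt, "nzb") == []

    def test_both_genotypes_fails_uniqueness(self):
        pt = self._table({("nzb", 11): True, ("nzb", 19): True,
                          ("c57", 11): True, ("c57", 19): True})
        assert call_cyclic_proteins(pt, "nzb") == []

    def test_target_pattern_called(self):
        pt = self._table({("nzb", 11): True, ("nzb", 19): True})
        assert call_cyclic_proteins(pt, "nzb") == ["p"]

    def test_invariant_to_replicate_order_and_rescaling(self, clean_proteome):
        pt, _ = clean_proteome
        base = call_cyclic_proteins(pt, "nzb")
        shuffled = pt.values.iloc[:, ::-1]
        pt2 = ProteomeTable(values=shuffled, floor=pt.floor, min_detect=pt.min_detect)
        assert call_cyclic_proteins(pt2, "nzb") == base
        pt3 = ProteomeTable(values=pt.values * 100.0, floor=pt.floor, min_detect=pt.min_detect)
        assert call_cyclic_proteins(pt3, "nzb") == base

    def test_missing_genotype_rejected(self, clean_proteome):
        with pytest.raises(InputError, match="genotype"):
            call_cyclic_proteins(clean_proteome[0], "balbc")


class TestDifferentialProteins:
    def test_identical_groups_null(self, clean_proteome):
        pt, _ = clean_proteome
        res = differential_proteins(pt, [("nzb", 11)], [("nzb", 11)])
        tested = res[res.tested]
        assert np.allclose(tested.p, 1.0)
        assert not tested.significant.any()

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(0)
        cols = pd.MultiIndex.from_product(
            [["a"], [3, 11], [1, 2, 3, 4, 5]], names=["genotype", "timepoint", "replicate"]
        )
        base = rng.normal(20, 0.25, size=(30, 10))
        base[:5, 5:] += 2.0  # 4-fold shift in 5 proteins at the second timepoint
        pt = ProteomeTable(values=pd.DataFrame(np.exp2(base), columns=cols))
        res = differential_proteins(pt, [("a", 3)], [("a", 11)])
        assert res.significant[:5].all()
        assert res.log2fc[:5].mean() == pytest.approx(2.0, abs=0.3)

    def test_underpowered_proteins_reported_untested(self):
        cols = pd.MultiIndex.from_product(
            [["a"], [3, 11], [1, 2]], names=["genotype", "timepoint", "replicate"]
        )
        vals = pd.DataFrame([[np.nan, 8.0, 9.0, 10.0]], index=["p"], columns=cols)
        res = differential_proteins(ProteomeTable(values=vals, min_detect=1), [("a", 3)], [("a", 11)])
        assert not res.loc["p", "tested"]
        assert np.isnan(res.loc["p", "q"])


class TestClusterTimepoints:
    def test_equal_pairs_partition_exactly(self, rng):
        t1 = rng.normal(size=200)
        t2 = t1 + rng.normal(scale=1.0, size=200)
        profiles = pd.DataFrame({"3m": t1, "11m": t2, "14m": t1, "19m": t2})
        res = cluster_timepoints(profiles)
        assert res.partition_sets() == {frozenset({"3m", "14m"}), frozenset({"11m", "19m"})}

    def test_monotone_drift_splits_farthest_endpoint(self, rng):
        base = rng.normal(6, 1, size=2000)
        slope = rng.normal(0, 0.5, size=2000)
        profiles = pd.DataFrame(
            {f"{tp}m": base + k * slope for k, tp in enumerate((3, 11, 14, 19))}
        )
        res = cluster_timepoints(profiles)
        assert frozenset({"3m"}) in res.partition_sets()

    def test_constant_profile_rejected(self):
        profiles = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 3.0]})
        with pytest.raises(InputError, match="b"):
            cluster_timepoints(profiles)

    def test_newick_contains_all_labels(self, small_timecourse):
        tc, _ = small_timecourse
        res = cluster_timepoints(tc.replicate_means().rename(columns=lambda t: f"{t}m"))
        for lab in ("3m", "11m", "14m", "19m"):
            assert lab in res.newick
        assert res.newick.endswith(";")
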