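"""Within-pair discordance statistics and dynamics classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import twindrift as td
from tests.conftest import make_samples


class TestPairDiscordance:
    def test_absolute_difference(self, two_pair_samples):
        m = pd.DataFrame(0.5, index=["cg0"], columns=two_pair_samples.index)
        m.loc["cg0", "P01-T1-birth-r1"] = 0.30
        m.loc["cg0", "P01-T2-birth-r1"] = 0.55
        d = td.pair_discordance(m, two_pair_samples, "birth")
        assert d.loc["cg0", "P01"] == pytest.approx(0.25)

    def test_symmetric_in_twin_order(self, two_pair_samples):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.random((6, len(two_pair_samples))),
                         index=[f"cg{i}" for i in range(6)],
                         columns=two_pair_samples.index)
        d1 = td.pair_discordance(m, two_pair_samples, "birth")
        swapped = two_pair_samples.copy()
        swapped["twin_index"] = 3 - swapped["twin_index"]
        d2 = td.pair_discordance(m, swapped, "birth")
        np.testing.assert_allclose(d1, d2)

    def test_identical_cotwins_zero(self, two_pair_samples):
        m = pd.DataFrame(0.4, index=["cg0", "cg1"],
                         columns=two_pair_samples.index)
        d = td.pair_discordance(m, two_pair_samples, "m18")
        np.testing.assert_allclose(d, 0.0)

    def test_incomplete_pair_dropped(self, two_pair_samples):
        cols = [c for c in two_pair_samples.index if c != "P02-T1-birth-r1"]
        m = pd.DataFrame(0.4, index=["cg0"], columns=cols)
        d = td.pair_discordance(m, two_pair_samples.loc[cols], "birth")
        assert list(d.columns) == ["P01"]

    def test_no_complete_pair_rejected(self, two_pair_samples):
        cols = [c for c in two_pair_samples.index
                if "T2" not in c]
        m = pd.DataFrame(0.4, index=["cg0"], columns=cols)
        with pytest.raises(ValueError, match="no complete pair"):
            td.pair_discordance(m, two_pair_samples.loc[cols], "birth")


class TestResidualDiscordance:
    def test_two_member_closed_form(self):
        samples = make_samples(1, timepoints=("birth",))
        m = pd.DataFrame([[1.0, 0.0]], index=["cg0"], columns=samples.index)
        r = td.residual_discordance(m, samples)
        np.testing.assert_allclose(r.loc["cg0"], [0.5, -0.5])

    def test_residuals_sum_to_zero_per_group(self, small_cohort):
        qc = td.run_qc(small_cohort)
        r = td.residual_discordance(qc.m_norm, qc.samples)
        meta = qc.samples
        key = meta["pair_id"] + "|" + meta["timepoint"]
        for _, cols in meta.groupby(key.values).groups.items():
            np.testing.assert_allclose(r[list(cols)].sum(axis=1), 0.0,
                                       atol=1e-9)

    def test_singleton_group_warns_zero(self):
        samples = make_samples(1, timepoints=("birth",)).iloc[:1]
        m = pd.DataFrame([[2.0]], index=["cg0"], columns=samples.index)
        with pytest.warns(UserWarning, match="singleton"):
            r = td.residual_discordance(m, samples)
        assert r.iloc[0, 0] == 0.0


class TestCountingAndDistance:
    def test_strictly_greater_counting(self):
        assert td.count_discordant([0.25, 0.10, 0.21]) == 2
        assert td.count_discordant([0.2, 0.2]) == 0
        assert td.count_discordant(np.zeros(5)) == 0

    def test_three_four_five(self):
        assert td.euclidean_distance([0.3, 0.0], [0.0, 0.4]) == pytest.approx(
            0.5)

    def test_identical_vectors_zero(self):
        v = np.random.default_rng(1).random(10)
        assert td.euclidean_distance(v, v) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            td.euclidean_distance([1.0], [1.0, 2.0])

    @given(st.lists(st.floats(min_value=-1, max_value=1), min_size=1,
                    max_size=20))
    def test_adding_nonzero_difference_increases_distance(self, diffs):
        a = np.array(diffs)
        b = np.zeros_like(a)
        d1 = td.euclidean_distance(a, b)
        d2 = td.euclidean_distance(np.append(a, 0.5), np.append(b, 0.0))
        assert d2 > d1

    def test_distance_consistent_with_probe_discordance(self, default_run):
        """ED^2 equals the sum of squared probe-wise discordances."""
        beta = default_run.qc.beta_norm
        samples = default_run.qc.samples
        d = td.pair_discordance(beta, samples, "birth")
        prof = default_run.disc.profiles
        for pid in d.columns:
            assert prof.loc[pid, "ed_birth"] ** 2 == pytest.approx(
                float((d[pid] ** 2).sum()), rel=1e-9)


class TestDeltaDiscordance:
    def test_elementwise_difference(self):
        b = pd.Series([0.1, 0.2], index=["cg0", "cg1"])
        m = pd.Series([0.3, 0.2], index=["cg0", "cg1"])
        delta, summary = td.delta_discordance(b, m)
        assert delta["cg0"] == pytest.approx(0.2)
        assert summary["median"] == pytest.approx(0.1)

    def test_identical_vectors_zero_delta(self):
        v = pd.Series([0.5, 0.6])
        delta, summary = td.delta_discordance(v, v)
        assert (delta == 0).all()
        assert summary["central_mass_lt_0.05"] == 1.0

    def test_mismatch_rejected(self):
        with pytest.raises(ValueError, match="matched"):
            td.delta_discordance(pd.Series([0.1], index=["a"]),
                                 pd.Series([0.1], index=["b"]))

    def test_null_simulation_centred_on_zero(self):
        """With lambda = 1 everywhere the delta-discordance distribution is
        centred about zero (10 seeds)."""
        means = []
        for seed in range(10):
            cfg = td.default_config(
                n_probes=1000, n_pairs=4, n_planted_dmrs=0,
                frac_age_affected=0.0, detection_failure_rate=0.0,
                pair_dynamics={f"P{k + 1:02d}": 1.0 for k in range(4)},
                seed=300 + seed)
            cohort = td.simulate_cohort(cfg)
            _, _, summary = td.pair_profiles(cohort.beta, cohort.samples)
            means.append(summary["mean"])
        assert all(abs(m) < 0.005 for m in means)


class TestDynamicsClassification:
    @pytest.mark.parametrize("eds,label", [
        ((300, 400), "drift"),
        ((400, 300), "converge"),
        ((300, 310), "stable"),
    ])
    def test_relative_threshold(self, eds, label):
        assert td.classify_pair_dynamics(*eds) == label

    def test_zero_birth_distance_stable_with_warning(self):
        with pytest.warns(UserWarning, match="zero distance"):
            assert td.classify_pair_dynamics(0.0, 5.0) == "stable"

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            td.classify_pair_dynamics(-1.0, 2.0)

    def test_planted_dynamics_recovered(self, default_run):
        prof = default_run.disc.profiles
        truth = default_run.cohort.truth.pairs
        acc = (prof["dynamics"]
               == truth.loc[prof.index, "dynamics"]).mean()
        assert acc >= 0.9


class TestRankedLists:
    def test_gene_keeps_best_rank(self):
        metric = pd.Series({"cg0": 0.9, "cg1": 0.5, "cg2": 0.8})
        gmap = pd.Series({"cg0": "GENEA", "cg1": "GENEA", "cg2": "GENEB"})
        assert td.rank_probes_for_ontology(metric, gmap) == ["GENEA", "GENEB"]

    def test_strictly_decreasing_metric_preserves_order(self):
        metric = pd.Series({"cg0": 3.0, "cg1": 2.0, "cg2": 1.0})
        gmap = pd.Series({"cg0": "A", "cg1": "B", "cg2": "C"})
        assert td.rank_probes_for_ontology(metric, gmap) == ["A", "B", "C"]

    def test_ties_broken_by_probe_id(self):
        metric = pd.Series({"cgB": 1.0, "cgA": 1.0})
        gmap = pd.Series({"cgA": "GA", "cgB": "GB"})
        assert td.rank_probes_for_ontology(metric, gmap) == ["GA", "GB"]

    def test_intergenic_probes_excluded(self):
        metric = pd.Series({"cg0": 2.0, "cg1": 1.0})
        gmap = pd.Series({"cg0": "", "cg1": "GENEC"})
        assert td.rank_probes_for_ontology(metric, gmap) == ["GENEC"]

    def test_empty_gene_map_rejected(self):
        with pytest.raises(ValueError, match="empty gene map"):
            td.rank_probes_for_ontology(pd.Series({"cg0": 1.0}),
                                        pd.Series({"cg0": ""}))


class TestWeightDiscordance:
    @pytest.mark.parametrize("w1,w2,expect", [
        (3000, 3000, 0.0),
        (4000, 2000, 50.0),
        (2000, 4000, 50.0),
    ])
    def test_percent_formula(self, w1, w2, expect):
        assert td.weight_discordance(w1, w2) == pytest.approx(expect)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            td.weight_discordance(0, 100)


def test_delta_discordance_smaller_than_delta_beta(default_run):
    """Age-related change outpaces discordance change when planted age
    effects exceed the drift scaling (distribution medians)."""
    delta = default_run.disc.delta
    stringent = default_run.dm.admps["stringent"]
    res = default_run.dm.result
    med_delta_disc = float(np.abs(delta.to_numpy()).ravel().mean())
    med_delta_beta = float(res.loc[stringent, "delta_beta"].abs().median())
    assert med_delta_disc < med_delta_beta
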