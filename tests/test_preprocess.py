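"""QC filters, beta/M transforms and normalization."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import twindrift as td
from twindrift.preprocess import collapse_replicates


def _detp(values, probes=None, samples=None):
    arr = np.asarray(values, dtype=float)
    probes = probes or [f"cg{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=probes, columns=samples)


class TestDetectionFilters:
    def test_all_zero_everything_retained(self):
        d = _detp(np.zeros((4, 3)))
        assert td.filter_probes_by_detection(d).all()
        assert td.filter_samples_by_detection(d).all()

    def test_single_bad_entry_removes_probe(self):
        v = np.zeros((3, 4))
        v[1, 2] = 0.01
        keep = td.filter_probes_by_detection(_detp(v))
        assert list(keep) == [True, False, True]

    def test_probe_boundary_exactly_threshold_retained(self):
        keep = td.filter_probes_by_detection(_detp(np.full((2, 2), 0.001)))
        assert keep.all()

    def test_sample_mean_above_threshold_removed(self):
        v = np.zeros((10, 3))
        v[:, 1] = 0.10
        keep = td.filter_samples_by_detection(_detp(v))
        assert list(keep) == [True, False, True]

    def test_sample_boundary_exactly_threshold_retained(self):
        keep = td.filter_samples_by_detection(_detp(np.full((5, 2), 0.05)))
        assert keep.all()

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            td.filter_probes_by_detection(pd.DataFrame())
        with pytest.raises(ValueError):
            td.filter_samples_by_detection(pd.DataFrame())

    def test_filters_idempotent(self, small_cohort):
        keep1 = td.filter_probes_by_detection(small_cohort.detp)
        sub = small_cohort.detp.loc[keep1]
        keep2 = td.filter_probes_by_detection(sub)
        assert keep2.all()


class TestSexChromosomeRemoval:
    def test_counts(self, tiny_manifest):
        mat = pd.DataFrame(np.random.default_rng(0).random((12, 2)),
                           index=tiny_manifest.index, columns=["a", "b"])
        out = td.drop_sex_chromosomes(mat, tiny_manifest)
        assert len(out) == 10
        assert not tiny_manifest.loc[out.index, "chrom"].isin(
            ["chrX", "chrY"]).any()

    def test_identity_without_sex_probes(self, tiny_manifest):
        auto = tiny_manifest[tiny_manifest["chrom"] == "chr1"]
        mat = pd.DataFrame(np.ones((len(auto), 2)), index=auto.index,
                           columns=["a", "b"])
        out = td.drop_sex_chromosomes(mat, tiny_manifest)
        pd.testing.assert_frame_equal(out, mat)

    def test_all_sex_probes_warns_and_empties(self, tiny_manifest):
        x = tiny_manifest[tiny_manifest["chrom"] == "chrX"]
        mat = pd.DataFrame(np.ones((len(x), 1)), index=x.index,
                           columns=["a"])
        with pytest.warns(UserWarning, match="sex chromosomes"):
            out = td.drop_sex_chromosomes(mat, tiny_manifest)
        assert out.empty

    def test_unknown_probe_named_in_error(self, tiny_manifest):
        mat = pd.DataFrame([[0.5]], index=["cgMISSING"], columns=["a"])
        with pytest.raises(KeyError, match="cgMISSING"):
            td.drop_sex_chromosomes(mat, tiny_manifest)


class TestBetaMTransforms:
    @pytest.mark.parametrize("beta,m", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)])
    def test_known_values(self, beta, m):
        assert td.beta_to_m(np.array([beta]))[0] == pytest.approx(m, abs=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            td.beta_to_m(np.array([1.2]))

    @given(st.floats(min_value=1e-5, max_value=1 - 1e-5))
    def test_round_trip(self, b):
        assert td.m_to_beta(td.beta_to_m(np.array([b])))[0] == pytest.approx(
            b, abs=1e-9)


class TestDesignBiasAdjustment:
    def test_all_type_i_identity_with_warning(self, tiny_manifest):
        man = tiny_manifest.copy()
        man["design_type"] = "I"
        beta = pd.DataFrame(np.random.default_rng(1).random((12, 3)),
                            index=man.index, columns=list("abc"))
        with pytest.warns(UserWarning, match="one design class"):
            out = td.adjust_design_bias(beta, man)
        pd.testing.assert_frame_equal(out, beta)

    def test_compression_is_undone(self):
        """Quantile mapping shrinks the type II vs type I distribution gap
        introduced by the simulated intensity bias."""
        cfg = td.default_config(n_probes=4000, n_pairs=2, n_planted_dmrs=0,
                                design_ii_compression=0.3, seed=21)
        cohort = td.simulate_cohort(cfg)
        man = cohort.manifest
        beta = cohort.beta
        m2 = man["design_type"] == "II"
        m1 = man["design_type"] == "I"
        q = np.linspace(0.05, 0.95, 19)

        def gap(b):
            col = b.iloc[:, 0]
            return np.abs(np.quantile(col[m1], q)
                          - np.quantile(col[m2], q)).mean()

        adjusted = td.adjust_design_bias(beta, man)
        assert gap(adjusted) < 0.5 * gap(beta)

    def test_rank_order_preserved_within_strata(self, small_cohort):
        """The quantile map is monotone, so within each island-relation
        stratum the type II rank order is unchanged."""
        man = small_cohort.manifest
        out = td.adjust_design_bias(small_cohort.beta, man)
        for rel in man["island_relation"].unique():
            m2 = ((man["design_type"] == "II")
                  & (man["island_relation"] == rel)).to_numpy()
            for col in small_cohort.beta.columns[:3]:
                before = small_cohort.beta.loc[m2, col].rank()
                after = out.loc[m2, col].rank()
                assert (before == after).all()


class TestQuantileNormalization:
    def test_identical_columns_unchanged(self):
        col = np.sort(np.random.default_rng(3).random(50))
        m = pd.DataFrame({"a": col, "b": col})
        out = td.quantile_normalize_between_arrays(m)
        np.testing.assert_allclose(out.to_numpy(), m.to_numpy(), atol=1e-12)

    def test_sorted_columns_identical_after(self):
        m = pd.DataFrame(np.random.default_rng(4).random((100, 5)))
        out = td.quantile_normalize_between_arrays(m)
        ref = np.sort(out.iloc[:, 0].to_numpy())
        for j in range(1, 5):
            np.testing.assert_allclose(np.sort(out.iloc[:, j]), ref,
                                       atol=1e-12)

    def test_ranks_preserved(self):
        m = pd.DataFrame(np.random.default_rng(5).random((60, 3)))
        out = td.quantile_normalize_between_arrays(m)
        for j in range(3):
            assert (m.iloc[:, j].rank() == out.iloc[:, j].rank()).all()

    def test_ties_get_mean_of_reference(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 3.0], "b": [0.0, 2.0, 4.0]})
        out = td.quantile_normalize_between_arrays(m)
        # reference = mean of sorted columns = (0.5, 1.5, 3.5); the tied
        # pair in column a takes mean(0.5, 1.5) = 1.0
        np.testing.assert_allclose(out["a"], [1.0, 1.0, 3.5])
        np.testing.assert_allclose(out["b"], [0.5, 1.5, 3.5])

    def test_single_sample_identity_with_warning(self):
        m = pd.DataFrame({"a": [0.1, 0.2]})
        with pytest.warns(UserWarning, match="fewer than 2"):
            out = td.quantile_normalize_between_arrays(m)
        pd.testing.assert_frame_equal(out, m)

    def test_matches_limma_reference(self, tmp_path):
        """Independent oracle: limma::normalizeQuantiles on tie-free data."""
        rng = np.random.default_rng(8)
        m = pd.DataFrame(rng.normal(size=(40, 6)))
        ours = td.quantile_normalize_between_arrays(m)
        csv = tmp_path / "m.csv"
        m.to_csv(csv, index=False)
        out_csv = tmp_path / "out.csv"
        script = textwrap.dedent(f"""
            suppressMessages(library(limma))
            x <- as.matrix(read.csv("{csv}"))
            write.csv(normalizeQuantiles(x), "{out_csv}", row.names=FALSE)
        """)
        subprocess.run(["Rscript", "-e", script], check=True,
                       capture_output=True)
        theirs = pd.read_csv(out_csv).to_numpy()
        np.testing.assert_allclose(ours.to_numpy(), theirs, atol=1e-8)


class TestReplicateCollapse:
    def test_replicates_averaged(self, small_cohort):
        withrep = td.inject_technical_replicates(small_cohort, ["P01"], 0.05,
                                                 seed=2)
        collapsed, meta = collapse_replicates(withrep.beta, withrep.samples)
        a = withrep.beta["P01-T1-birth-r1"]
        b = withrep.beta["P01-T1-birth-r2"]
        np.testing.assert_allclose(collapsed["P01-T1-birth"], (a + b) / 2)
        assert "replicate_id" not in meta.columns


class TestRunQC:
    def test_qc_removes_exactly_truth_flagged_probes(self, default_run):
        cohort = default_run.cohort
        truth = cohort.truth.probes
        keep = td.filter_probes_by_detection(cohort.detp)
        assert (~keep == truth["qc_fail"]).all()

    def test_report_counts_consistent(self, default_run):
        rep = default_run.qc.report
        assert (rep["n_probes_input"]
                - rep["n_probes_failed_detection"]
                - rep["n_probes_sex_chrom"]
                == rep["n_probes_retained"])
        assert rep["n_samples_retained"] == default_run.qc.m_norm.shape[1]
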