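"""Unit tests for probe collapsing, moderated t, fixed-effect pooling,
BH adjustment and DEG selection."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from revsig.meta_signature import (DiseaseSignature, ExpressionStudy,
                                   bh_adjust, collapse_probes,
                                   fixed_effect_meta, intersect_genes,
                                   moderated_t, select_degs)


def bh_bruteforce(p):
    """Textbook step-up: q_(i) = min_{j>=i} m * p_(j) / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_i, i in enumerate(order, start=1):
        candidates = [m * p[j] / rank_j
                      for rank_j, j in enumerate(order, start=1)
                      if rank_j >= rank_i]
        q[i] = min(1.0, min(candidates))
    return q


class TestCollapseProbes:
    def test_highest_iqr_probe_wins(self):
        m = pd.DataFrame(
            {"s1": [0.0, 0.0], "s2": [4.0, 2.0], "s3": [2.0, 1.0],
             "s4": [6.0, 3.0]},
            index=["pA", "pB"])  # IQRs 3.0 vs 1.5
        pm = pd.Series({"pA": "G", "pB": "G"})
        out = collapse_probes(m, pm)
        assert list(out.index) == ["G"]
        assert (out.loc["G"] == m.loc["pA"]).all()

    def test_single_probe_passthrough(self):
        m = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["p1"])
        out = collapse_probes(m, pd.Series({"p1": "G"}))
        assert (out.loc["G"] == m.loc["p1"]).all()

    def test_exact_tie_broken_by_probe_id(self):
        # equal IQR (1.5 each); lexicographically smaller probe id wins
        m = pd.DataFrame([[1.0, 2.0, 3.0, 4.0], [11.0, 12.0, 13.0, 14.0]],
                         index=["pZ", "pA"], columns=list("abcd"))
        out = collapse_probes(m, pd.Series({"pZ": "G", "pA": "G"}))
        assert out.loc["G", "a"] == 11.0  # pA retained

    def test_unmapped_probes_dropped(self):
        m = pd.DataFrame({"s1": [1.0, 2.0], "s2": [3.0, 4.0]},
                         index=["p1", "p2"])
        out = collapse_probes(m, pd.Series({"p1": "G1"}))
        assert list(out.index) == ["G1"]

    def test_empty_matrix_errors(self):
        with pytest.raises(ValueError, match="empty"):
            collapse_probes(pd.DataFrame(), pd.Series(dtype=object))


class TestIntersectGenes:
    def test_common_index(self):
        a = pd.DataFrame({"s": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        b = pd.DataFrame({"s": [4.0, 5.0, 6.0]}, index=["b", "c", "d"])
        out = intersect_genes([a, b])
        assert [list(m.index) for m in out] == [["b", "c"], ["b", "c"]]

    def test_single_study_unchanged(self):
        a = pd.DataFrame({"s": [1.0, 2.0]}, index=["b", "a"])
        (out,) = intersect_genes([a])
        assert set(out.index) == {"a", "b"}

    def test_disjoint_errors(self):
        a = pd.DataFrame({"s": [1.0]}, index=["a"])
        b = pd.DataFrame({"s": [1.0]}, index=["b"])
        with pytest.raises(ValueError, match="empty"):
            intersect_genes([a, b])


class TestModeratedT:
    def test_textbook_pooled_t(self):
        m = pd.DataFrame([[0.0, 1.0, 2.0, 3.0, 4.0, 5.0]] , index=["g"],
                         columns=["T0", "T1", "T2", "N0", "N1", "N2"])
        labels = pd.Series(["tumor"] * 3 + ["normal"] * 3, index=m.columns)
        st_ = ExpressionStudy(matrix=m, labels=labels, platform_id="x")
        res = moderated_t(st_, prior_df=0)
        assert res.loc["g", "log2fc"] == pytest.approx(-3.0)
        assert res.loc["g", "s2"] == pytest.approx(1.0)
        assert res.loc["g", "t_mod"] == pytest.approx(-3.674, abs=5e-4)

    def test_zero_prior_df_equals_ordinary_t(self, tiny_study):
        from scipy import stats
        res = moderated_t(tiny_study, prior_df=0)
        t_cols = tiny_study.group_columns("tumor")
        n_cols = tiny_study.group_columns("normal")
        ref = stats.ttest_ind(tiny_study.matrix[t_cols],
                              tiny_study.matrix[n_cols], axis=1)
        np.testing.assert_allclose(res["t_mod"], ref.statistic, atol=1e-10)
        np.testing.assert_allclose(res["p"], ref.pvalue, atol=1e-10)

    def test_infinite_prior_df_shrinks_to_prior(self, tiny_study):
        res = moderated_t(tiny_study, prior_df=np.inf)
        assert res["s2_post"].nunique() == 1

    def test_degenerate_all_zero_variance(self):
        m = pd.DataFrame([[1.0] * 6, [2.0] * 6], index=["g1", "g2"],
                         columns=["T0", "T1", "T2", "N0", "N1", "N2"])
        labels = pd.Series(["tumor"] * 3 + ["normal"] * 3, index=m.columns)
        with pytest.raises(ValueError, match="degenerate"):
            moderated_t(ExpressionStudy(matrix=m, labels=labels,
                                        platform_id="x"))

    def test_too_few_samples_errors(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"],
                         columns=["T0", "N0", "N1"])
        labels = pd.Series(["tumor", "normal", "normal"], index=m.columns)
        with pytest.raises(ValueError, match="tumor"):
            moderated_t(ExpressionStudy(matrix=m, labels=labels,
                                        platform_id="x"))

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript unavailable")
    def test_matches_limma_ebayes(self, tmp_path):
        """Empirical-Bayes shrinkage agrees with the reference
        implementation (limma) to near machine precision."""
        rng = np.random.default_rng(42)
        n_genes, n1, n2 = 150, 4, 5
        vals = (rng.normal(7, 1, (n_genes, n1 + n2))
                * rng.uniform(0.5, 2, (n_genes, 1)))
        genes = [f"g{i}" for i in range(n_genes)]
        samples = [f"T{i}" for i in range(n1)] + [f"N{i}" for i in range(n2)]
        m = pd.DataFrame(vals, index=genes, columns=samples)
        labels = pd.Series(["tumor"] * n1 + ["normal"] * n2, index=samples)
        res = moderated_t(ExpressionStudy(matrix=m, labels=labels,
                                          platform_id="x"))
        m.to_csv(tmp_path / "expr.tsv", sep="\t")
        script = (
            'suppressMessages(library(limma));'
            'x <- as.matrix(read.delim("expr.tsv", row.names=1));'
            f'design <- cbind(Int=1, tumor=c(rep(1,{n1}), rep(0,{n2})));'
            'fit <- eBayes(lmFit(x, design));'
            'write.csv(data.frame(t=fit$t[,"tumor"], '
            'p=fit$p.value[,"tumor"], d0=fit$df.prior), "limma_out.csv")')
        subprocess.run(["Rscript", "-e", script], cwd=tmp_path, check=True,
                       capture_output=True)
        lim = pd.read_csv(tmp_path / "limma_out.csv", index_col=0)
        assert res.attrs["d0"] == pytest.approx(lim["d0"].iloc[0], rel=1e-9)
        np.testing.assert_allclose(res["t_mod"], lim["t"], atol=1e-9)
        np.testing.assert_allclose(res["p"], lim["p"], atol=1e-9)


class TestFixedEffectMeta:
    @staticmethod
    def _frame(fc, v):
        return pd.DataFrame({"log2fc": fc, "v": v},
                            index=[f"g{i}" for i in range(len(fc))])

    def test_symmetric_studies(self):
        out = fixed_effect_meta([self._frame([1.0], [0.1]),
                                 self._frame([1.0], [0.1])])
        assert out["combined_log2fc"].iloc[0] == pytest.approx(1.0)
        assert out["combined_v"].iloc[0] == pytest.approx(0.05)

    def test_weighted_mean_hand_example(self):
        out = fixed_effect_meta([self._frame([1.0], [0.1]),
                                 self._frame([2.0], [0.2])])
        assert out["combined_log2fc"].iloc[0] == pytest.approx(4.0 / 3.0)
        assert out["combined_v"].iloc[0] == pytest.approx(1.0 / 15.0)

    def test_single_study_identity(self):
        out = fixed_effect_meta([self._frame([1.5], [0.3])])
        assert out["combined_log2fc"].iloc[0] == pytest.approx(1.5)
        assert out["combined_v"].iloc[0] == pytest.approx(0.3)

    def test_combined_variance_below_min(self):
        rng = np.random.default_rng(3)
        frames = [self._frame(rng.normal(0, 1, 50),
                              rng.uniform(0.05, 0.5, 50))
                  for _ in range(3)]
        out = fixed_effect_meta(frames)
        vmin = np.min([f["v"].to_numpy() for f in frames], axis=0)
        assert (out["combined_v"].to_numpy() < vmin).all()

    def test_nonpositive_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            fixed_effect_meta([self._frame([1.0], [0.0])])

    def test_mismatched_index_errors(self):
        a = self._frame([1.0], [0.1])
        b = self._frame([1.0], [0.1]).rename(index={"g0": "h0"})
        with pytest.raises(ValueError, match="gene index"):
            fixed_effect_meta([a, b])


class TestBhAdjust:
    def test_stepup_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_and_constant(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]),
                                   [0.2, 0.2, 0.2])

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=100))
    def test_matches_bruteforce_and_statsmodels(self, p):
        q = bh_adjust(p)
        np.testing.assert_allclose(q, bh_bruteforce(p), atol=1e-12)
        from statsmodels.stats.multitest import multipletests
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, q_sm, atol=1e-12)


class TestSelectDegs:
    @staticmethod
    def _meta(fc, q):
        return pd.DataFrame({"combined_log2fc": fc, "q": q},
                            index=[f"g{i}" for i in range(len(fc))])

    def test_threshold_boundaries(self):
        meta = self._meta([1.6, 1.4, -1.8, -1.2], [5e-4] * 4)
        sig = select_degs(meta)
        assert sig.up_genes == ["g0"]
        assert sig.down_genes == ["g2"]

    def test_q_gate(self):
        meta = self._meta([2.0, 2.0], [5e-4, 5e-3])
        sig = select_degs(meta)
        assert sig.up_genes == ["g0"]

    def test_sorted_by_abs_fc(self):
        meta = self._meta([1.6, 2.5, 1.9], [1e-5] * 3)
        sig = select_degs(meta)
        assert sig.up_genes == ["g1", "g2", "g0"]

    def test_disjoint_invariant(self):
        with pytest.raises(ValueError, match="overlap"):
            DiseaseSignature(
                up=pd.DataFrame(index=["g1"],
                                data={"combined_log2fc": [2.0], "q": [0.0]}),
                down=pd.DataFrame(index=["g1"],
                                  data={"combined_log2fc": [-2.0],
                                        "q": [0.0]}))
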