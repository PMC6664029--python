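"""Unit and property tests for ranking, KS enrichment, RGES, sRGES
summarization, similarity metrics and condition contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_profile
from revsig.meta_signature import DiseaseSignature
from revsig.signature_scoring import (RankedProfile, compute_rges,
                                      condition_contrast, enrichment_score,
                                      estimate_condition_offsets,
                                      rank_profile, score_profiles,
                                      similarity_metrics, summarize_rges)


def ranked_from_order(genes):
    genes = np.asarray(genes)
    return RankedProfile(genes=genes,
                         position=pd.Series(np.arange(1, len(genes) + 1),
                                            index=genes))


def es_walk_oracle(n, positions):
    """Left-to-right running-sum oracle for the KS enrichment statistic.

    Walks ranks 1..n tracking the hit CDF; a is the largest lead of the
    hit CDF over the uniform reference, b the largest lead of the
    reference over the hit CDF just before each hit.
    """
    hits = set(positions)
    t = len(hits)
    a = -np.inf
    b = -np.inf
    seen = 0
    for i in range(1, n + 1):
        b = max(b, i / n - seen / t)
        if i in hits:
            seen += 1
            a = max(a, seen / t - i / n)
    return a if a > b else -b


class TestRankProfile:
    def test_descending_order(self):
        p = make_profile({"g1": 2.0, "g2": -1.0, "g3": 0.5})
        assert list(rank_profile(p).genes) == ["g1", "g3", "g2"]

    def test_tie_broken_by_gene_id(self):
        p = make_profile({"gB": 1.0, "gA": 1.0, "gC": 2.0})
        assert list(rank_profile(p).genes) == ["gC", "gA", "gB"]

    def test_all_equal_gives_gene_order(self):
        p = make_profile({"g3": 0.0, "g1": 0.0, "g2": 0.0})
        assert list(rank_profile(p).genes) == ["g1", "g2", "g3"]

    def test_non_gold_rejected(self):
        with pytest.raises(ValueError, match="gold"):
            rank_profile(make_profile({"g1": 1.0}, gold=False))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            rank_profile(make_profile({"g1": np.nan, "g2": 1.0}))


class TestEnrichmentScore:
    def test_top_positions_hand_example(self):
        ranked = ranked_from_order([f"g{i}" for i in range(1, 11)])
        # positions {1, 2}: a = max(0.4, 0.8) = 0.8, b = 0.1
        assert enrichment_score(ranked, {"g1", "g2"}) == pytest.approx(0.8)

    def test_bottom_positions_hand_example(self):
        ranked = ranked_from_order([f"g{i}" for i in range(1, 11)])
        # positions {9, 10}: a = 0, b = 0.9
        assert enrichment_score(ranked, {"g9", "g10"}) == pytest.approx(-0.9)

    def test_saturated_set_scores_zero(self):
        ranked = ranked_from_order([f"g{i}" for i in range(1, 11)])
        assert enrichment_score(ranked, {f"g{i}" for i in range(1, 11)}) == 0.0

    def test_empty_set_errors(self):
        ranked = ranked_from_order(["g1", "g2"])
        with pytest.raises(ValueError, match="empty"):
            enrichment_score(ranked, set())

    def test_unknown_gene_errors(self):
        ranked = ranked_from_order(["g1", "g2"])
        with pytest.raises(ValueError, match="universe"):
            enrichment_score(ranked, {"gX"})

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_walk_oracle(self, data):
        n = data.draw(st.integers(5, 50))
        t = data.draw(st.integers(1, min(10, n - 1)))
        positions = data.draw(
            st.lists(st.integers(1, n), min_size=t, max_size=t,
                     unique=True))
        ranked = ranked_from_order([f"g{i}" for i in range(1, n + 1)])
        gene_set = {f"g{i}" for i in positions}
        assert enrichment_score(ranked, gene_set) == pytest.approx(
            es_walk_oracle(n, positions), abs=1e-12)


class TestComputeRges:
    def _signature(self, up, down):
        return DiseaseSignature(
            up=pd.DataFrame({"combined_log2fc": 2.0, "q": 1e-5},
                            index=list(up)),
            down=pd.DataFrame({"combined_log2fc": -2.0, "q": 1e-5},
                              index=list(down)))

    def test_opposite_signs_compose(self):
        ranked = ranked_from_order([f"g{i}" for i in range(1, 11)])
        sig = self._signature(up=["g9", "g10"], down=["g1", "g2"])
        rec = compute_rges(ranked, sig)
        assert rec.es_up == pytest.approx(-0.9)
        assert rec.es_down == pytest.approx(0.8)
        assert rec.rges == pytest.approx(-1.7)

    def test_same_sign_zeroed(self):
        ranked = ranked_from_order([f"g{i}" for i in range(1, 11)])
        sig = self._signature(up=["g1", "g2"], down=["g3", "g4"])
        rec = compute_rges(ranked, sig)
        assert np.sign(rec.es_up) == np.sign(rec.es_down)
        assert rec.rges == 0.0

    def test_perfect_reversal_below_minus_1_5(self):
        n, n_up, n_down = 978, 53, 42
        genes = [f"g{i:04d}" for i in range(1, n + 1)]
        up = genes[-n_up:]       # bottom of the ranking
        down = genes[:n_down]    # top of the ranking
        ranked = ranked_from_order(genes)
        rec = compute_rges(ranked, self._signature(up=up, down=down))
        assert rec.rges <= -1.5
        assert rec.rges == pytest.approx(-(926 + 936) / 978, abs=1e-9)

    def test_empty_restricted_set_names_the_set(self):
        ranked = ranked_from_order(["g1", "g2", "g3"])
        sig = self._signature(up=["gX"], down=["g1"])
        with pytest.raises(ValueError, match="up"):
            compute_rges(ranked, sig)

    def test_vectorized_scoring_matches_per_profile(self, small_signature):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(1, 30)]
        profiles = [make_profile(dict(zip(genes, rng.normal(size=29))),
                                 profile_id=f"p{k}", compound=f"c{k}")
                    for k in range(8)]
        table = score_profiles(profiles, small_signature)
        for p, (_, row) in zip(profiles, table.iterrows()):
            rec = compute_rges(rank_profile(p), small_signature, p)
            assert row["rges"] == pytest.approx(rec.rges, abs=1e-12)
            assert row["es_up"] == pytest.approx(rec.es_up, abs=1e-12)


class TestSummarizeRges:
    @staticmethod
    def _records(rows):
        return pd.DataFrame(
            rows, columns=["profile_id", "compound", "cell_line", "dose_um",
                           "duration_h", "is_gold", "es_up", "es_down",
                           "rges"])

    def test_single_reference_profile_identity(self):
        rec = self._records([("p1", "c1", "PC3", 10.0, 24.0, True,
                              -0.6, 0.6, -1.2)])
        out = summarize_rges(rec)
        assert out.loc[0, "srges"] == pytest.approx(-1.2)

    def test_mean_of_reference_profiles(self):
        rec = self._records([
            ("p1", "c1", "PC3", 10.0, 24.0, True, 0, 0, -1.0),
            ("p2", "c1", "PC3", 10.0, 24.0, True, 0, 0, -0.5)])
        assert summarize_rges(rec).loc[0, "srges"] == pytest.approx(-0.75)

    def test_dose_offset_adjustment_hand_example(self):
        rec = self._records([
            ("p1", "c1", "PC3", 10.0, 24.0, True, 0, 0, -1.0),
            ("p2", "c1", "PC3", 1.0, 24.0, True, 0, 0, -0.4)])
        d_dose, d_time = estimate_condition_offsets(rec)
        assert d_dose == pytest.approx(0.6)
        assert d_time == 0.0
        # adjusted low-dose record: -0.4 - 0.6 = -1.0
        assert summarize_rges(rec).loc[0, "srges"] == pytest.approx(-1.0)

    def test_non_gold_profiles_excluded(self):
        rec = self._records([
            ("p1", "c1", "PC3", 10.0, 24.0, True, 0, 0, -1.0),
            ("p2", "c1", "PC3", 10.0, 24.0, False, 0, 0, 5.0)])
        assert summarize_rges(rec).loc[0, "srges"] == pytest.approx(-1.0)

    def test_all_non_gold_errors(self):
        rec = self._records([("p1", "c1", "PC3", 10.0, 24.0, False,
                              0, 0, -1.0)])
        with pytest.raises(ValueError, match="gold"):
            summarize_rges(rec)

    def test_record_order_invariance(self):
        rng = np.random.default_rng(9)
        rows = [(f"p{i}", f"c{i % 5}", "PC3",
                 float(rng.choice([1.0, 10.0])),
                 float(rng.choice([6.0, 24.0])), True, 0.0, 0.0,
                 float(rng.normal())) for i in range(40)]
        rec = self._records(rows)
        out1 = summarize_rges(rec)
        out2 = summarize_rges(rec.sample(frac=1, random_state=1))
        pd.testing.assert_frame_equal(out1, out2)

    def test_sorted_ascending_by_srges(self):
        rec = self._records([
            ("p1", "c1", "PC3", 10.0, 24.0, True, 0, 0, 0.5),
            ("p2", "c2", "PC3", 10.0, 24.0, True, 0, 0, -1.5)])
        out = summarize_rges(rec)
        assert list(out["compound"]) == ["c2", "c1"]


class TestSimilarityMetrics:
    def test_identical_vectors(self):
        x = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        res = similarity_metrics(x, x)
        assert res == pytest.approx((1.0, 1.0, 1.0))

    def test_negated_vector(self):
        x = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        res = similarity_metrics(x, -x)
        assert res.spearman == pytest.approx(-1.0)
        assert res.pearson == pytest.approx(-1.0)
        assert res.cosine == pytest.approx(-1.0)

    def test_spearman_hand_example(self):
        x = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        y = pd.Series([1.0, 3.0, 2.0], index=list("abc"))
        assert similarity_metrics(x, y).spearman == pytest.approx(0.5)

    def test_constant_vector_flagged(self):
        x = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        y = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        res = similarity_metrics(x, y)
        assert np.isnan(res.spearman) and np.isnan(res.pearson)
        assert np.isfinite(res.cosine)

    def test_too_few_shared_genes_errors(self):
        x = pd.Series([1.0, 2.0], index=list("ab"))
        with pytest.raises(ValueError, match="shared"):
            similarity_metrics(x, x)


class TestConditionContrast:
    @staticmethod
    def _records(doses, rges):
        return pd.DataFrame({
            "profile_id": [f"p{i}" for i in range(len(doses))],
            "compound": "c1", "cell_line": "PC3", "dose_um": doses,
            "duration_h": 24.0, "is_gold": True, "rges": rges})

    def test_identical_groups_p_one(self):
        rec = self._records([1.0] * 5 + [10.0] * 5,
                            [0.1, 0.2, 0.3, 0.4, 0.5] * 2)
        assert condition_contrast(rec, "dose").p_value == pytest.approx(1.0)

    def test_separated_groups_small_p(self):
        rec = self._records([1.0] * 10 + [10.0] * 10,
                            list(range(1, 11)) + list(range(11, 21)))
        res = condition_contrast(rec, "dose")
        assert res.p_value < 1e-3

    def test_underpopulated_level_errors(self):
        rec = self._records([1.0, 10.0, 10.0], [0.1, 0.2, 0.3])
        with pytest.raises(ValueError, match=">=2"):
            condition_contrast(rec, "dose")

    def test_unknown_factor_errors(self):
        rec = self._records([1.0, 1.0, 10.0, 10.0], [0.1, 0.2, 0.3, 0.4])
        with pytest.raises(ValueError, match="factor"):
            condition_contrast(rec, "nope")


class TestBoundsProperties:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_es_and_rges_bounds(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 2 ** 31 - 1)))
        n = data.draw(st.integers(10, 80))
        genes = [f"g{i}" for i in range(n)]
        order = rng.permutation(genes)
        ranked = ranked_from_order(order)
        k_up = data.draw(st.integers(1, max(1, n // 4)))
        k_down = data.draw(st.integers(1, max(1, n // 4)))
        chosen = rng.choice(genes, size=k_up + k_down, replace=False)
        sig = DiseaseSignature(
            up=pd.DataFrame({"combined_log2fc": 2.0, "q": 0.0},
                            index=list(chosen[:k_up])),
            down=pd.DataFrame({"combined_log2fc": -2.0, "q": 0.0},
                              index=list(chosen[k_up:])))
        rec = compute_rges(ranked, sig)
        assert -1.0 <= rec.es_up <= 1.0
        assert -1.0 <= rec.es_down <= 1.0
        assert -2.0 <= rec.rges <= 2.0
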