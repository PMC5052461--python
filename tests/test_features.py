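"""Feature engine: sessions, IRS, enrichment, IC, landmarks, matrices."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom

import geoseek as gs
from geoseek.config import SEMANTIC_GROUPS
from geoseek.features import (LandmarkResolver, Selections,
                              assign_landmark_category, day_specificity,
                              select_enriched_tokens, session_durations)

from conftest import SMALL_FEATURES, records_frame


class TestSessionize:
    def test_gap_rule_hand_trace(self):
        # searches at 0, 600, 5000 with a 1800 s gap -> sessions of
        # durations 600 and 0
        durs = session_durations([0, 600, 5000], 1800)
        assert list(durs) == [600.0, 0.0]

    def test_single_search_session(self):
        assert list(session_durations([42], 1800)) == [0.0]

    def test_all_within_gap_one_session(self):
        durs = session_durations([0, 1000, 2000, 2500], 1800)
        assert list(durs) == [2500.0]


class TestIntervalReductionScore:
    def test_two_searches_score_exactly_one(self):
        assert gs.interval_reduction_score([0, 300]) == 1.0
        assert gs.interval_reduction_score([1234]) == 1.0
        assert gs.interval_reduction_score([]) == 1.0

    def test_equal_intervals_neutral(self):
        assert gs.interval_reduction_score([0, 100, 200, 300]) == pytest.approx(1.0)

    def test_hand_computed_shortening(self):
        # deltas 100, 50 -> single ratio 0.5 -> 0.1 + 0.9*0.5 = 0.55
        assert gs.interval_reduction_score([0, 100, 150], w=0.1) \
            == pytest.approx(0.55)

    def test_zero_interval_clamped(self):
        # deltas 100, 0 -> ratio clamped at 0.01
        score = gs.interval_reduction_score([0, 100, 100], w=0.1)
        assert score == pytest.approx(0.1 + 0.9 * 0.01)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            gs.interval_reduction_score([-5, 10, 20])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(0, 10_000), min_size=3, max_size=12),
           st.floats(0.05, 0.5))
    def test_shrinking_below_one_growing_above(self, deltas_raw, w):
        ts = np.cumsum([0] + sorted(set(deltas_raw), reverse=True))
        if len(ts) < 3 or len(set(np.diff(ts))) < 2:
            return
        shrinking = gs.interval_reduction_score(ts, w=w)
        growing = gs.interval_reduction_score(ts.max() - ts[::-1], w=w)
        assert shrinking < 1.0 < growing


class TestFisherEnrichment:
    def test_matches_exhaustive_hypergeometric_oracle(self):
        """Fisher p-values equal a two-sided hypergeometric-tail summation
        on all 2x2 tables with margins <= 30 (>= 200 tables)."""
        rng = np.random.default_rng(5)
        checked = 0
        for _ in range(400):
            n_pat = int(rng.integers(2, 31))
            n_ctl = int(rng.integers(2, 31))
            a = int(rng.integers(0, n_pat + 1))
            c = int(rng.integers(0, n_ctl + 1))
            item_users = {"tok": ({f"p{i}" for i in range(a)}
                                  | {f"c{i}" for i in range(c)})}
            pats = {f"p{i}" for i in range(n_pat)}
            ctls = {f"c{i}" for i in range(n_ctl)}
            res = gs.fisher_enrichment(item_users, pats, ctls, k=1, alpha=0.05)
            p_fisher = float(res.table["p"].iloc[0])
            # oracle: sum of probabilities of all tables with fixed margins
            # whose probability is <= that of the observed table
            K, N, n = a + c, n_pat + n_ctl, n_pat
            dist = hypergeom(N, K, n)
            support = np.arange(max(0, K - (N - n)), min(K, n) + 1)
            pmf = dist.pmf(support)
            p_oracle = float(pmf[pmf <= dist.pmf(a) * (1 + 1e-9)].sum())
            assert p_fisher == pytest.approx(p_oracle, abs=1e-10)
            checked += 1
        assert checked >= 200

    def test_strong_token_selected_null_token_not(self):
        pats = {f"p{i}" for i in range(100)}
        ctls = {f"c{i}" for i in range(100)}
        item_users = {
            "strong": {f"p{i}" for i in range(90)} | {f"c{i}" for i in range(10)},
            "null": {f"p{i}" for i in range(50)} | {f"c{i}" for i in range(50)},
        }
        res = gs.fisher_enrichment(item_users, pats, ctls, k=5, alpha=0.05)
        assert res.selected == ["strong"]
        null_row = res.table.set_index("item").loc["null"]
        assert null_row["p"] > 0.9

    def test_truncation_at_k(self):
        pats = {f"p{i}" for i in range(60)}
        ctls = {f"c{i}" for i in range(60)}
        item_users = {f"t{j}": {f"p{i}" for i in range(55)}
                      for j in range(150)}
        res = gs.fisher_enrichment(item_users, pats, ctls, k=100, alpha=0.05)
        assert len(res.selected) == 100 and not res.shortfall

    def test_shortfall_flagged(self):
        pats, ctls = {"p1", "p2"}, {"c1", "c2"}
        res = gs.fisher_enrichment({"t": {"p1"}}, pats, ctls, k=10)
        assert res.shortfall and len(res.selected) < 10


class TestSemanticGroups:
    def test_single_group_token(self, toy_lexicon):
        recs = records_frame([("u", 0, 0.0, 0.0, ("broad", "x"))])
        counts = gs.semantic_group_counts(recs, toy_lexicon)
        assert counts == {"disease": 1, "drug": 0, "device": 0, "procedure": 0}

    def test_multi_group_token_counts_in_both(self, toy_lexicon):
        recs = records_frame([("u", 0, 0.0, 0.0, ("dual",))])
        counts = gs.semantic_group_counts(recs, toy_lexicon)
        assert counts["drug"] == 1 and counts["procedure"] == 1
        assert counts["disease"] == 0

    def test_no_medical_tokens_all_zero(self, toy_lexicon):
        recs = records_frame([("u", 0, 0.0, 0.0, ("hello", "world"))])
        assert all(v == 0 for v in
                   gs.semantic_group_counts(recs, toy_lexicon).values())


class TestInformationContent:
    def test_root_ic_zero(self, toy_lexicon):
        from geoseek.lexicon import ROOT
        assert toy_lexicon.concept_ic(ROOT) == pytest.approx(0.0)

    def test_leaf_ic_direct_evaluation(self, toy_lexicon):
        # leaf aggregated freq 1, root total 1000 -> ln(1000)
        assert toy_lexicon.information_content("narrow") \
            == pytest.approx(math.log(1000), abs=1e-9)

    def test_day_specificity_max_and_mean(self, toy_lexicon):
        recs = records_frame([
            ("u", 0, 0.0, 0.0, ("broad",)),
            ("u", 10, 0.0, 0.0, ("narrow",)),
            ("u", 20, 0.0, 0.0, ("plain",)),
        ])
        ic_b = toy_lexicon.information_content("broad")
        ic_n = toy_lexicon.information_content("narrow")
        assert day_specificity(recs, toy_lexicon, "max") == pytest.approx(ic_n)
        assert day_specificity(recs, toy_lexicon, "mean") \
            == pytest.approx((ic_b + ic_n + 0.0) / 3)

    def test_unmapped_day_scores_zero(self, toy_lexicon):
        recs = records_frame([("u", 0, 0.0, 0.0, ("plain",))])
        assert day_specificity(recs, toy_lexicon) == 0.0


class TestCategorizationAgreement:
    def test_noiseless_all_groups_perfect(self, toy_lexicon):
        truth = {"broad": True, "narrow": True, "dual": True}
        recs = records_frame([
            ("u", 0, 0.0, 0.0, ("broad",)),
            ("u", 1, 0.0, 0.0, ("plain",)),
        ])
        assert gs.categorization_agreement(
            recs, toy_lexicon, SEMANTIC_GROUPS, truth) == 1.0

    def test_empty_groups_degenerate(self, toy_lexicon):
        truth = {"broad": True}
        recs = records_frame([
            ("u", 0, 0.0, 0.0, ("broad",)),
            ("u", 1, 0.0, 0.0, ("plain",)),
            ("u", 2, 0.0, 0.0, ("plain",)),
        ])
        # everything predicted non-health; agreement = non-health fraction
        assert gs.categorization_agreement(recs, toy_lexicon, [], truth) \
            == pytest.approx(2 / 3)

    def test_dropping_device_group_improves_agreement(self):
        """With half the device terms secretly non-medical, labeling with
        disease/drug/procedure only beats labeling with all four groups in
        >= 18 of 20 seeds (the device-misattribution direction)."""
        wins = 0
        for seed in range(20):
            w = gs.generate_world(gs.WorldConfig(seed=300 + seed,
                                                 device_noise_rate=0.5,
                                                 lexicon_size=150))
            rec, _ = gs.generate_users(
                w, gs.CohortConfig(n_patients=0, n_controls=10,
                                   days_per_user=42, seed=400 + seed,
                                   health_search_prob=0.35))
            with_device = gs.categorization_agreement(
                rec, w.lexicon, SEMANTIC_GROUPS, w.term_truth)
            without = gs.categorization_agreement(
                rec, w.lexicon, ("disease", "drug", "procedure"), w.term_truth)
            wins += without > with_device
        assert wins >= 18


class TestLandmarkResolver:
    def test_exact_coordinates_return_that_landmark(self, world, resolver):
        lm = world.landmarks.iloc[5]
        cat, toks = assign_landmark_category(lm["lat"], lm["lon"], resolver)
        assert cat == lm["category"]
        assert toks == lm["name"].split()

    def test_rounded_coordinates_share_resolution(self, world, resolver):
        lm = world.landmarks.iloc[3]
        a = resolver.resolve([lm["lat"] + 2e-6], [lm["lon"]])
        b = resolver.resolve([lm["lat"] - 2e-6], [lm["lon"]])
        assert a["category"].iloc[0] == b["category"].iloc[0]
        assert a["name"].iloc[0] == b["name"].iloc[0]

    def test_nearest_of_ten_equals_global_nearest(self, world, resolver):
        rng = np.random.default_rng(9)
        lat0, lon0, lat1, lon1 = world.config.map_extent
        lats = rng.uniform(lat0, lat1, 1000)
        lons = rng.uniform(lon0, lon1, 1000)
        res = resolver.resolve(lats, lons)
        # exhaustive oracle over the whole gazetteer, on rounded coords
        rl = np.round(lats, 4)
        ro = np.round(lons, 4)
        d = gs.haversine_distance(rl[:, None], ro[:, None],
                                  world.landmarks["lat"].to_numpy()[None, :],
                                  world.landmarks["lon"].to_numpy()[None, :])
        oracle = world.landmarks["name"].to_numpy()[np.argmin(d, axis=1)]
        assert (res["name"].to_numpy() == oracle).all()

    def test_ten_closest_sorted(self, world, resolver):
        out = resolver.ten_closest(40.0, 116.4)
        assert len(out) == 10
        assert (np.diff(out["dist_m"]) >= 0).all()


class TestMatrices:
    def test_daywise_column_arithmetic(self, world, cohort, resolver):
        """41 x (5 general + 4 groups + 1 specificity + k tokens + k cats)."""
        sel = Selections(tokens=[f"tok{i}" for i in range(7)],
                         categories=["health", "park"],
                         name_tokens=["clinic"])
        m = gs.build_matrices(cohort["windows"][:6], world.lexicon, resolver,
                              sel, SMALL_FEATURES)
        expected = 41 * (5 + 4 + 1 + 7 + 2)
        assert m.daywise.shape[1] - 1 == expected  # minus the label column
        assert set(m.daywise_categories.values()) \
            == {"general", "semantic", "location"}

    def test_matrices_deterministic(self, world, cohort, resolver, matrices):
        m1, sel = matrices
        m2 = gs.build_matrices(cohort["windows"], world.lexicon, resolver,
                               sel, SMALL_FEATURES)
        pd.testing.assert_frame_equal(m1.daywise, m2.daywise)
        pd.testing.assert_frame_equal(m1.aggregate, m2.aggregate)

    def test_unseen_user_receives_selected_columns(self, world, cohort, resolver):
        sel = Selections(tokens=["never_used_token"], categories=["health"],
                         name_tokens=["inn"])
        m = gs.build_matrices(cohort["windows"][:3], world.lexicon, resolver,
                              sel, SMALL_FEATURES)
        tok_cols = [c for c in m.daywise.columns
                    if c.startswith("sem_tok_never_used_token")]
        assert len(tok_cols) == 41
        assert (m.daywise[tok_cols] == 0).all().all()

    def test_daywise_sums_match_window_recount(self, world, cohort, matrices):
        """Oracle re-aggregation: summed daywise counts equal an independent
        full-window recount."""
        m, sel = matrices
        from geoseek.config import HEALTH_GROUPS
        health = world.lexicon.terms_in_groups(HEALTH_GROUPS)
        w = cohort["windows"][0]
        n_cols = [c for c in m.daywise.columns if c.startswith("gen_n_searches__")]
        h_cols = [c for c in m.daywise.columns
                  if c.startswith("gen_n_health_searches__")]
        assert m.daywise.loc[w.user_id, n_cols].sum() == len(w.records)
        recount = sum(any(t in health for t in toks) for toks in w.records["tokens"])
        assert m.daywise.loc[w.user_id, h_cols].sum() == recount

    def test_aggregate_binary_indicators(self, matrices):
        m, sel = matrices
        for t in sel.name_tokens:
            assert set(m.aggregate[f"loc_name_{t}"].unique()) <= {0.0, 1.0}

    def test_no_cross_user_dependence(self, world, cohort, resolver, matrices):
        """Dropping other users leaves one user's feature row unchanged."""
        m, sel = matrices
        w = cohort["windows"][4]
        solo = gs.build_matrices([w], world.lexicon, resolver, sel,
                                 SMALL_FEATURES)
        pd.testing.assert_series_equal(solo.daywise.loc[w.user_id],
                                       m.daywise.loc[w.user_id])

    def test_post_endpoint_perturbation_invariance(self, world, cohort, resolver,
                                                   matrices):
        """Leakage check: altering records at/after the endpoint and
        re-partitioning leaves the matrices byte-identical."""
        m, sel = matrices
        records = cohort["records"].copy()
        ep = {w.user_id: w.endpoint_time for w in cohort["windows"]}
        post = records.apply(
            lambda r: r["ts"] >= ep.get(r["user_id"], np.inf), axis=1)
        records.loc[post, "tokens"] = pd.Series(
            [("perturbed", "junk")] * int(post.sum()), index=records.index[post])
        windows2 = []
        for w in cohort["windows"]:
            urecs = records[records["user_id"] == w.user_id]
            windows2.append(gs.partition_window(
                urecs, w.endpoint_time, w.label, cohort["policy"]))
        m2 = gs.build_matrices(windows2, world.lexicon, resolver, sel,
                               SMALL_FEATURES)
        pd.testing.assert_frame_equal(m.daywise, m2.daywise)
        pd.testing.assert_frame_equal(m.aggregate, m2.aggregate)

    def test_selection_uses_training_windows_only(self, cohort):
        """Permuting labels of held-out windows cannot change the fit."""
        windows = cohort["windows"]
        train = windows[:40]
        held_out = windows[40:]
        r1 = select_enriched_tokens(train, SMALL_FEATURES)
        for w in held_out:  # flip labels outside the training set
            w.label = "patient" if w.label == "control" else "control"
        try:
            r2 = select_enriched_tokens(train, SMALL_FEATURES)
        finally:
            for w in held_out:
                w.label = "patient" if w.label == "control" else "control"
        assert r1.selected == r2.selected
        pd.testing.assert_frame_equal(r1.table, r2.table)
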