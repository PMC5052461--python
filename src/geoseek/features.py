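"""Daywise and aggregate feature engineering over analysis windows.

Three feature categories are computed from each user's 41-search-day
analysis window:

* **general** — per-day search volume, health-related search volume, mean
  session duration, mean search-text length, and the interval reduction
  score (IRS) summarizing the shortening/lengthening of intervals between
  consecutive health-related searches within a day;
* **semantic** — per-day membership counts of searches in the disease,
  drug, device, and procedure semantic groups, daywise search specificity
  (information content of the most specific term), and per-day counts of
  tokens found enriched in patients vs controls by a Fisher exact test
  with Bonferroni correction;
* **location** — per-day counts of searches mapped to enriched landmark
  categories, and window-level binary indicators for enriched tokens in
  landmark names.

All enrichment selections are fitted on training users only; the schema of
the resulting matrices is fixed by the fitted selection, so unseen users
receive the same columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import FeatureConfig, HEALTH_GROUPS, SEMANTIC_GROUPS
from .errors import GeoseekError
from .geofence import AnalysisWindow, haversine_distance
from .lexicon import Lexicon

# ---------------------------------------------------------------------------
# sessions


def sessionize(ts, session_gap_s: float):
    """Assign session ids to time-sorted timestamps of one search day.

    Consecutive searches at most ``session_gap_s`` apart share a session
    (a 30-minute inactivity gap by default).  Returns an integer array of
    session ids starting at 0.
    """
    ts = np.asarray(ts, dtype=np.int64)
    if np.any(np.diff(ts) < 0):
        raise ValueError("timestamps must be sorted")
    if len(ts) == 0:
        return np.array([], dtype=int)
    new = np.concatenate([[True], np.diff(ts) > session_gap_s])
    return np.cumsum(new) - 1


def session_durations(ts, session_gap_s: float) -> np.ndarray:
    """Durations (last minus first timestamp) of each session; singletons are 0."""
    ts = np.asarray(ts, dtype=np.int64)
    sid = sessionize(ts, session_gap_s)
    if len(ts) == 0:
        return np.array([])
    out = []
    for s in np.unique(sid):
        t = ts[sid == s]
        out.append(float(t[-1] - t[0]))
    return np.array(out)


# ---------------------------------------------------------------------------
# interval reduction score


def interval_reduction_score(ts, w: float = 0.1,
                             clamp: tuple[float, float] = (0.01, 100.0)) -> float:
    """Interval reduction score of one search day's health-related searches.

    For a day with ``n <= 2`` searches the score is exactly 1.  For
    ``n >= 3`` searches at sorted times ``t_1..t_n`` with intervals
    ``D_i = t_{i+1} - t_i`` the score is

        mean over i of  [ w + (1 - w) * D_{i+1} / D_i ]

    so equal intervals give exactly 1, shrinking intervals give < 1 and
    growing intervals > 1, with the weight ``w`` (small, near 0.1) damping
    extreme ratios.  Each ratio is clamped to ``clamp`` to tame zero or
    enormous intervals; a 0/0 ratio (two coincident pairs) is neutral (1).
    """
    ts = np.asarray(ts, dtype=float)
    if np.any(ts < 0):
        raise ValueError("negative timestamps")
    ts = np.sort(ts)
    n = len(ts)
    if n <= 2:
        return 1.0
    d = np.diff(ts)
    num, den = d[1:], d[:-1]
    lo, hi = clamp
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = num / den
    ratio[np.isnan(ratio)] = 1.0          # 0/0: no change
    ratio = np.clip(ratio, lo, hi)
    return float(np.mean(w + (1.0 - w) * ratio))


# ---------------------------------------------------------------------------
# per-search annotations


def annotate_searches(records: pd.DataFrame, lexicon: Lexicon) -> pd.DataFrame:
    """Add per-search semantic columns derived from the lexicon.

    Adds ``is_health`` (any token in a disease/drug/procedure concept),
    ``text_len`` (token count), ``max_ic`` (information content of the most
    specific mapped term; 0 when no token maps), and one boolean column
    ``grp_<g>`` per semantic group.
    """
    out = records.copy()
    token_lists = out["tokens"].tolist()
    n = len(out)
    text_len = np.fromiter((len(t) for t in token_lists), dtype=int, count=n)
    max_ic = np.zeros(n)
    grp_flags = {g: np.zeros(n, dtype=bool) for g in SEMANTIC_GROUPS}
    health = np.zeros(n, dtype=bool)
    health_groups = set(HEALTH_GROUPS)
    groups_of = lexicon.term_semantic_groups
    ic_of = lexicon._term_ic
    for i, toks in enumerate(token_lists):
        best = 0.0
        for t in toks:
            gs = groups_of(t)
            if gs:
                for g in gs:
                    grp_flags[g][i] = True
                if gs & health_groups:
                    health[i] = True
                ic = ic_of.get(t, 0.0)
                if math.isfinite(ic) and ic > best:
                    best = ic
        max_ic[i] = best
    out["text_len"] = text_len
    out["is_health"] = health
    out["max_ic"] = max_ic
    for g in SEMANTIC_GROUPS:
        out[f"grp_{g}"] = grp_flags[g]
    return out


def semantic_group_counts(records: pd.DataFrame, lexicon: Lexicon) -> dict[str, int]:
    """Number of searches mapped to each semantic group.

    A search counts toward group g when any of its tokens maps to a concept
    in g; a single search may count toward several groups.
    """
    ann = annotate_searches(records, lexicon)
    return {g: int(ann[f"grp_{g}"].sum()) for g in SEMANTIC_GROUPS}


def day_specificity(records: pd.DataFrame, lexicon: Lexicon,
                    mode: str = "max") -> float:
    """Daywise search-specificity score.

    Per search: the information content of its most specific mapped term.
    The day score is the maximum over searches (default) or, optionally,
    the mean of the per-search maxima.  A day with no mapped term scores 0.
    """
    ann = annotate_searches(records, lexicon)
    vals = ann["max_ic"].to_numpy()
    if len(vals) == 0:
        return 0.0
    return float(vals.max() if mode == "max" else vals.mean())


def categorization_agreement(records: pd.DataFrame, lexicon: Lexicon,
                             included_groups, term_truth: dict[str, bool]) -> float:
    """Agreement between lexicon-based and reference health labeling.

    Each search is segregated as health-related iff any token maps to a
    concept in one of ``included_groups``; the reference label calls a
    search health-related iff it contains any token whose ground-truth
    label is health.  Returns the fraction of searches on which the two
    segregations agree.
    """
    included = set(included_groups)
    groups_of = lexicon.term_semantic_groups
    agree = 0
    for toks in records["tokens"]:
        pred = any(groups_of(t) & included for t in toks)
        ref = any(term_truth.get(t, False) for t in toks)
        agree += pred == ref
    return agree / len(records)


# ---------------------------------------------------------------------------
# Fisher enrichment


@dataclass
class EnrichmentResult:
    """Outcome of a Fisher-with-Bonferroni enrichment screen.

    ``table`` has one row per tested item with the 2x2 counts
    (n_pat_using, n_pat_not, n_ctl_using, n_ctl_not), the raw and
    Bonferroni-adjusted p-values, the log odds ratio, the enrichment
    direction, and a ``selected`` flag; ``selected`` lists the retained
    items in rank order.
    """

    table: pd.DataFrame
    selected: list[str]
    k_requested: int
    shortfall: bool = False


def _fisher_table(item_users: dict[str, set], pat: set, ctl: set) -> pd.DataFrame:
    n_pat, n_ctl = len(pat), len(ctl)
    rows = []
    for item in sorted(item_users):
        users = item_users[item]
        a = len(users & pat)
        c = len(users & ctl)
        rows.append((item, a, n_pat - a, c, n_ctl - c))
    return pd.DataFrame(rows, columns=["item", "n_pat_using", "n_pat_not",
                                       "n_ctl_using", "n_ctl_not"])


def _fisher_pvalues(tab: pd.DataFrame) -> np.ndarray:
    ps = np.empty(len(tab))
    for i, (a, b, c, d) in enumerate(zip(tab["n_pat_using"], tab["n_pat_not"],
                                         tab["n_ctl_using"], tab["n_ctl_not"])):
        ps[i] = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
    return ps


def fisher_enrichment(item_users: dict[str, set], patients: set, controls: set,
                      k: int, alpha: float = 0.05) -> EnrichmentResult:
    """Select up to ``k`` items over-/under-represented in patients.

    ``item_users`` maps each candidate item to the set of users that used
    it.  A two-sided Fisher exact test is run per item on the users-using
    vs users-not 2x2 table, Bonferroni-corrected over all tested items;
    significant items are ranked by adjusted p ascending, ties broken by
    larger absolute log odds ratio then lexicographic item id, and the top
    ``k`` are retained.  When fewer than ``k`` items are significant all
    of them are returned and ``shortfall`` is set.
    """
    tab = _fisher_table(item_users, patients, controls)
    if tab.empty:
        return EnrichmentResult(tab.assign(p=[], p_adj=[], log_odds=[],
                                           direction=[], significant=[],
                                           selected=[]), [], k, True)
    m = len(tab)
    tab["p"] = _fisher_pvalues(tab)
    tab["p_adj"] = np.minimum(tab["p"] * m, 1.0)
    a, b = tab["n_pat_using"], tab["n_pat_not"]
    c, d = tab["n_ctl_using"], tab["n_ctl_not"]
    tab["log_odds"] = np.log((a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5)))
    tab["direction"] = np.where(tab["log_odds"] > 0, "patient", "control")
    tab["significant"] = tab["p_adj"] <= alpha
    ranked = tab[tab["significant"]].sort_values(
        by=["p_adj", "log_odds", "item"],
        key=lambda s: -s.abs() if s.name == "log_odds" else s)
    selected = ranked["item"].head(k).tolist()
    tab["selected"] = tab["item"].isin(selected)
    return EnrichmentResult(table=tab, selected=selected, k_requested=k,
                            shortfall=len(selected) < k)


def _two_level_enrichment(item_users: dict[str, set],
                          item_user_days: dict[str, set],
                          pat: set, ctl: set, n_days: int, k: int,
                          alpha: float) -> EnrichmentResult:
    """Union of a user-level and a day-level Fisher screen.

    Analysis 1 tests, per item, how many patients vs controls ever used it
    inside their windows.  Analysis 2 compares day-level usage: the number
    of patient user-days vs control user-days on which the item was used
    (each user contributes ``n_days`` days), probing items whose usage
    *frequency* rather than mere presence differs.  Both are Bonferroni
    corrected over the items tested; the union is ranked by the smaller of
    the two adjusted p-values (ties: larger |log odds|, then item id) and
    the best ``k`` are kept.
    """
    res_user = fisher_enrichment(item_users, pat, ctl,
                                 k=len(item_users), alpha=alpha)
    pat_days = {(u, d) for u in pat for d in range(1, n_days + 1)}
    ctl_days = {(u, d) for u in ctl for d in range(1, n_days + 1)}
    res_day = fisher_enrichment(item_user_days, pat_days, ctl_days,
                                k=len(item_user_days), alpha=alpha)

    tu = res_user.table.set_index("item")
    td = res_day.table.set_index("item")
    items = tu.index
    merged = pd.DataFrame({
        "item": items,
        "n_pat_using": tu["n_pat_using"],
        "n_pat_not": tu["n_pat_not"],
        "n_ctl_using": tu["n_ctl_using"],
        "n_ctl_not": tu["n_ctl_not"],
        "p_user_adj": tu["p_adj"],
        "p_day_adj": td["p_adj"].reindex(items).fillna(1.0),
        "log_odds": tu["log_odds"],
        "direction": tu["direction"],
    }).reset_index(drop=True)
    merged["p_adj"] = merged[["p_user_adj", "p_day_adj"]].min(axis=1)
    merged["significant"] = merged["p_adj"] <= alpha
    ranked = merged[merged["significant"]].sort_values(
        by=["p_adj", "log_odds", "item"],
        key=lambda s: -s.abs() if s.name == "log_odds" else s)
    selected = ranked["item"].head(k).tolist()
    merged["selected"] = merged["item"].isin(selected)
    return EnrichmentResult(table=merged, selected=selected, k_requested=k,
                            shortfall=len(selected) < k)


def select_enriched_tokens(windows: list[AnalysisWindow], config: FeatureConfig,
                           ) -> EnrichmentResult:
    """Two-analysis enriched-token screen on training windows."""
    pat = {w.user_id for w in windows if w.label == "patient"}
    ctl = {w.user_id for w in windows if w.label == "control"}
    token_users: dict[str, set] = {}
    token_user_days: dict[str, set] = {}
    n_days = 0
    for w in windows:
        n_days = max(n_days, w.n_days)
        for toks, day in zip(w.records["tokens"], w.records["day_bucket"]):
            for t in toks:
                token_users.setdefault(t, set()).add(w.user_id)
                token_user_days.setdefault(t, set()).add((w.user_id, day))
    return _two_level_enrichment(token_users, token_user_days, pat, ctl,
                                 n_days, config.n_enriched_tokens,
                                 config.bonferroni_alpha)


# ---------------------------------------------------------------------------
# landmarks


class LandmarkResolver:
    """Nearest-landmark lookup with rounded-coordinate caching.

    Coordinates are rounded to ``coord_round_places`` decimals (4 by
    default, ~11 m of precision) and each unique rounded pair is resolved
    once: the 10 closest landmarks are ranked by great-circle distance and
    the nearest one's category and name are attached to every search at
    that rounded location.
    """

    def __init__(self, landmarks: pd.DataFrame, config: FeatureConfig,
                 earth_radius_m: float = 6_371_000.0, n_closest: int = 10):
        if len(landmarks) == 0:
            raise GeoseekError("landmark gazetteer is empty")
        self.landmarks = landmarks.reset_index(drop=True)
        self.places = config.coord_round_places
        self.earth_radius_m = earth_radius_m
        self.n_closest = n_closest
        self._cache: dict[tuple[float, float], int] = {}

    def ten_closest(self, lat: float, lon: float) -> pd.DataFrame:
        """The ``n_closest`` landmarks ranked by distance to (lat, lon)."""
        d = haversine_distance(lat, lon, self.landmarks["lat"].to_numpy(),
                               self.landmarks["lon"].to_numpy(), self.earth_radius_m)
        order = np.argsort(d, kind="stable")[: self.n_closest]
        out = self.landmarks.iloc[order].copy()
        out["dist_m"] = d[order]
        return out.reset_index(drop=True)

    def resolve(self, lat, lon) -> pd.DataFrame:
        """Vectorized nearest-landmark category and name per coordinate."""
        lat = np.round(np.asarray(lat, dtype=float), self.places)
        lon = np.round(np.asarray(lon, dtype=float), self.places)
        pairs = np.stack([lat, lon], axis=1)
        uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)
        idx = np.empty(len(uniq), dtype=int)
        missing = []
        for i, (la, lo) in enumerate(uniq):
            key = (float(la), float(lo))
            if key in self._cache:
                idx[i] = self._cache[key]
            else:
                missing.append(i)
        if missing:
            mlat = uniq[missing, 0]
            mlon = uniq[missing, 1]
            llat = self.landmarks["lat"].to_numpy()
            llon = self.landmarks["lon"].to_numpy()
            chunk = max(1, 10_000_000 // len(self.landmarks))
            for start in range(0, len(missing), chunk):
                sl = slice(start, min(start + chunk, len(missing)))
                d = haversine_distance(mlat[sl, None], mlon[sl, None],
                                       llat[None, :], llon[None, :],
                                       self.earth_radius_m)
                nearest = np.argmin(d, axis=1)
                for j, near in zip(missing[start:start + len(nearest)], nearest):
                    idx[j] = near
                    self._cache[(float(uniq[j, 0]), float(uniq[j, 1]))] = int(near)
        chosen = idx[inverse]
        return pd.DataFrame({
            "category": self.landmarks["category"].to_numpy()[chosen],
            "name": self.landmarks["name"].to_numpy()[chosen],
        })


def assign_landmark_category(lat: float, lon: float, resolver: LandmarkResolver
                             ) -> tuple[str, list[str]]:
    """Nearest landmark's category and its name tokens for one coordinate."""
    res = resolver.resolve([lat], [lon])
    return res["category"].iloc[0], res["name"].iloc[0].split()


def select_enriched_location_items(windows: list[AnalysisWindow],
                                   resolver: LandmarkResolver,
                                   config: FeatureConfig
                                   ) -> tuple[EnrichmentResult, EnrichmentResult]:
    """Enriched landmark categories and location-name tokens (training only).

    Reuses the token Fisher machinery: a user (or user-day) "uses" a
    category when a search resolves to a landmark of that category, and a
    name token when the resolved landmark's name contains the token.
    """
    pat = {w.user_id for w in windows if w.label == "patient"}
    ctl = {w.user_id for w in windows if w.label == "control"}
    cat_users: dict[str, set] = {}
    cat_days: dict[str, set] = {}
    name_users: dict[str, set] = {}
    name_days: dict[str, set] = {}
    n_days = 0
    for w in windows:
        n_days = max(n_days, w.n_days)
        res = resolver.resolve(w.records["lat"].to_numpy(),
                               w.records["lon"].to_numpy())
        for cat, name, day in zip(res["category"], res["name"],
                                  w.records["day_bucket"]):
            cat_users.setdefault(cat, set()).add(w.user_id)
            cat_days.setdefault(cat, set()).add((w.user_id, day))
            for t in name.split():
                name_users.setdefault(t, set()).add(w.user_id)
                name_days.setdefault(t, set()).add((w.user_id, day))
    cats = _two_level_enrichment(cat_users, cat_days, pat, ctl, n_days,
                                 config.n_enriched_location_categories,
                                 config.bonferroni_alpha)
    names = _two_level_enrichment(name_users, name_days, pat, ctl, n_days,
                                  config.n_location_name_tokens,
                                  config.bonferroni_alpha)
    return cats, names


# ---------------------------------------------------------------------------
# matrix assembly


@dataclass
class Selections:
    """Training-split fits that fix the feature schema."""

    tokens: list[str]
    categories: list[str]
    name_tokens: list[str]
    token_result: EnrichmentResult | None = None
    category_result: EnrichmentResult | None = None
    name_token_result: EnrichmentResult | None = None


def fit_selections(train_windows: list[AnalysisWindow], resolver: LandmarkResolver,
                   config: FeatureConfig) -> Selections:
    """Fit every enrichment selection on the training windows only."""
    tok = select_enriched_tokens(train_windows, config)
    cats, names = select_enriched_location_items(train_windows, resolver, config)
    return Selections(tokens=tok.selected, categories=cats.selected,
                      name_tokens=names.selected, token_result=tok,
                      category_result=cats, name_token_result=names)


@dataclass
class FeatureMatrices:
    """Model-ready daywise and aggregate matrices with category tags."""

    daywise: pd.DataFrame            # index user_id, feature columns + 'label'
    aggregate: pd.DataFrame
    daywise_categories: dict[str, str] = field(default_factory=dict)
    aggregate_categories: dict[str, str] = field(default_factory=dict)

    def xy(self, which: str = "daywise") -> tuple[pd.DataFrame, pd.Series]:
        df = self.daywise if which == "daywise" else self.aggregate
        return df.drop(columns=["label"]), df["label"]


def _pivot(df: pd.DataFrame, value_col: str, aggfunc, users, n_days: int,
           name: str, fill) -> pd.DataFrame:
    wide = df.pivot_table(index="user_id", columns="day_bucket",
                          values=value_col, aggfunc=aggfunc)
    wide = wide.reindex(index=users, columns=range(1, n_days + 1))
    wide = wide.fillna(fill)
    wide.columns = [f"{name}__d{int(c):02d}" for c in wide.columns]
    return wide


def build_matrices(windows: list[AnalysisWindow], lexicon: Lexicon,
                   resolver: LandmarkResolver, selections: Selections,
                   config: FeatureConfig) -> FeatureMatrices:
    """Assemble the daywise and aggregate feature matrices.

    Daywise columns per day bucket: 5 general (searches, health searches,
    mean session duration, mean text length, IRS), 4 semantic-group counts,
    1 specificity, one count per selected token and per selected landmark
    category.  Aggregate columns: the window totals/means of the general
    and semantic quantities, token and category window counts, and one 0/1
    indicator per selected location-name token.  Column ordering is
    deterministic; rows are indexed by user id with a ``label`` column
    (patient=1, control=0).

    No feature of one user depends on another user's records, and only
    records inside the (strictly pre-endpoint) window are visible here.
    """
    n_days = config.n_window_days
    users = sorted(w.user_id for w in windows)
    labels = pd.Series({w.user_id: 1 if w.label == "patient" else 0
                        for w in windows}).reindex(users)

    parts = []
    for w in windows:
        ann = annotate_searches(w.records, lexicon)
        loc = resolver.resolve(ann["lat"].to_numpy(), ann["lon"].to_numpy())
        ann = ann.reset_index(drop=True)
        ann["category"] = loc["category"].to_numpy()
        ann["loc_name"] = loc["name"].to_numpy()
        parts.append(ann)
    big = pd.concat(parts, ignore_index=True)
    big = big.sort_values(["user_id", "ts"], kind="mergesort").reset_index(drop=True)

    # -- general ------------------------------------------------------------
    gb = big.groupby(["user_id", "day_bucket"])
    day_tables = {
        "gen_n_searches": (gb.size().rename("v").reset_index(), "v", "sum", 0.0),
    }
    health_counts = gb["is_health"].sum().rename("v").reset_index()
    text_len = gb["text_len"].mean().rename("v").reset_index()

    # sessions within a (user, day)
    user_day = big["user_id"].astype(str) + "|" + big["day_bucket"].astype(str)
    new_grp = np.concatenate([[True], user_day.to_numpy()[1:] != user_day.to_numpy()[:-1]])
    gap = np.concatenate([[True], np.diff(big["ts"].to_numpy()) > config.session_gap_s])
    sess_id = np.cumsum(new_grp | gap) - 1
    sess = pd.DataFrame({"user_id": big["user_id"], "day_bucket": big["day_bucket"],
                         "sess": sess_id, "ts": big["ts"]})
    per_sess = sess.groupby("sess").agg(
        user_id=("user_id", "first"), day_bucket=("day_bucket", "first"),
        dur=("ts", lambda t: float(t.max() - t.min())))
    sess_mean = per_sess.groupby(["user_id", "day_bucket"])["dur"].mean() \
        .rename("v").reset_index()
    n_sessions = per_sess.groupby(["user_id", "day_bucket"]).size() \
        .rename("v").reset_index()

    # IRS over the day's health-related searches
    health_recs = big[big["is_health"]]
    irs_rows = []
    for (u, d), grp in health_recs.groupby(["user_id", "day_bucket"]):
        irs_rows.append((u, d, interval_reduction_score(
            grp["ts"].to_numpy(), config.irs_weight, config.irs_ratio_clamp)))
    irs = pd.DataFrame(irs_rows, columns=["user_id", "day_bucket", "v"])

    # -- semantic -----------------------------------------------------------
    grp_counts = {g: gb[f"grp_{g}"].sum().rename("v").reset_index()
                  for g in SEMANTIC_GROUPS}
    spec_fun = "max" if config.specificity_mode == "max" else "mean"
    spec = gb["max_ic"].agg(spec_fun).rename("v").reset_index()

    tok_set = set(selections.tokens)
    tok_rows = []
    for uid_, day_, toks in zip(big["user_id"], big["day_bucket"], big["tokens"]):
        present = tok_set.intersection(toks)
        for t in present:
            tok_rows.append((uid_, day_, t))
    tok_df = pd.DataFrame(tok_rows, columns=["user_id", "day_bucket", "token"])

    # -- location -----------------------------------------------------------
    cat_set = set(selections.categories)
    cat_df = big[big["category"].isin(cat_set)][["user_id", "day_bucket", "category"]]

    # -- assemble daywise ---------------------------------------------------
    blocks: list[pd.DataFrame] = []
    categories: dict[str, str] = {}

    def add(df, name, fill, category, aggfunc="sum"):
        block = _pivot(df, "v", aggfunc, users, n_days, name, fill)
        for c in block.columns:
            categories[c] = category
        blocks.append(block)

    add(day_tables["gen_n_searches"][0], "gen_n_searches", 0.0, "general")
    add(health_counts, "gen_n_health_searches", 0.0, "general")
    add(sess_mean, "gen_mean_session_dur", 0.0, "general")
    add(text_len, "gen_mean_text_len", 0.0, "general")
    add(irs, "gen_irs", 1.0, "general")  # days with <=2 health searches score 1
    for g in SEMANTIC_GROUPS:
        add(grp_counts[g], f"sem_n_{g}", 0.0, "semantic")
    add(spec, "sem_specificity", 0.0, "semantic")
    for t in selections.tokens:
        sub = tok_df[tok_df["token"] == t].groupby(
            ["user_id", "day_bucket"]).size().rename("v").reset_index()
        add(sub, f"sem_tok_{t}", 0.0, "semantic")
    for cat in selections.categories:
        sub = cat_df[cat_df["category"] == cat].groupby(
            ["user_id", "day_bucket"]).size().rename("v").reset_index()
        add(sub, f"loc_cat_{cat}", 0.0, "location")

    daywise = pd.concat(blocks, axis=1)
    daywise.index.name = "user_id"
    daywise["label"] = labels

    # -- aggregate ----------------------------------------------------------
    gu = big.groupby("user_id")
    agg = pd.DataFrame(index=pd.Index(users, name="user_id"))
    agg_cat: dict[str, str] = {}

    def acol(name, series, category):
        agg[name] = series.reindex(users).fillna(0.0)
        agg_cat[name] = category

    acol("gen_n_searches", gu.size().astype(float), "general")
    acol("gen_n_health_searches", gu["is_health"].sum().astype(float), "general")
    acol("gen_mean_session_dur", per_sess.groupby("user_id")["dur"].mean(), "general")
    acol("gen_mean_text_len", gu["text_len"].mean(), "general")
    for g in SEMANTIC_GROUPS:
        acol(f"sem_n_{g}", gu[f"grp_{g}"].sum().astype(float), "semantic")
    acol("sem_specificity", gu["max_ic"].agg(spec_fun), "semantic")
    for t in selections.tokens:
        s = tok_df[tok_df["token"] == t].groupby("user_id").size().astype(float)
        acol(f"sem_tok_{t}", s, "semantic")
    for cat in selections.categories:
        s = cat_df[cat_df["category"] == cat].groupby("user_id").size().astype(float)
        acol(f"loc_cat_{cat}", s, "location")
    # binary presence of enriched name tokens anywhere in the window
    name_tok_users: dict[str, set] = {t: set() for t in selections.name_tokens}
    wanted = set(selections.name_tokens)
    for uid_, name in zip(big["user_id"], big["loc_name"]):
        for t in set(name.split()) & wanted:
            name_tok_users[t].add(uid_)
    for t in selections.name_tokens:
        agg[f"loc_name_{t}"] = [1.0 if u in name_tok_users[t] else 0.0 for u in users]
        agg_cat[f"loc_name_{t}"] = "location"
    agg["label"] = labels

    return FeatureMatrices(daywise=daywise, aggregate=agg,
                           daywise_categories=categories,
                           aggregate_categories=agg_cat)
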