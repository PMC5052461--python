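"""Offline/online utility evaluation of utilization predictions.

Offline: rank ad-exposed users by predicted health-care score and smooth
their conversion labels with a T-person sliding window — the *local show
conversion rate* — to read off how conversion probability varies with the
score.  Online: map each score to an ad-bid coefficient in (0.7, 1.3) and
compare treated vs control groups by the relative change in show
conversion rate and cost per action (CPA).

A conversion is a visit to facility F within ``lookahead_days`` (14) after
an impression from F, by a user with no visit to F within
``lookback_days`` (30) before that visit — i.e. a new utilization
plausibly linked to the ad, not a readmission.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import DAY_S, ConversionPolicy
from .errors import GeoseekError


def label_conversions(impressions: pd.DataFrame, visits: pd.DataFrame,
                      policy: ConversionPolicy) -> pd.Series:
    """Per-user converted flag (0/1) from impressions and visit events.

    A user converts iff some impression from facility F is followed by a
    visit to F within ``lookahead_days``, and the user had no visit to F
    within ``lookback_days`` before that visit.  Order of the impression
    stream is irrelevant.
    """
    users = pd.Index(sorted(impressions["user_id"].unique()), name="user_id")
    converted = pd.Series(0, index=users, dtype=int)
    if visits.empty or impressions.empty:
        return converted
    look_ahead = policy.lookahead_days * DAY_S
    look_back = policy.lookback_days * DAY_S

    merged = impressions.merge(
        visits[["user_id", "facility_id", "entry_time"]],
        on=["user_id", "facility_id"], how="inner")
    if merged.empty:
        return converted
    dt = merged["entry_time"] - merged["shown_time"]
    cand = merged[(dt > 0) & (dt <= look_ahead)]
    if cand.empty:
        return converted

    # prior-visit exclusion: any visit to the same facility within the
    # lookback window before the candidate converting visit
    vkey = visits.groupby(["user_id", "facility_id"])["entry_time"].apply(
        lambda s: np.sort(s.to_numpy()))
    ok_users = set()
    for row in cand.itertuples(index=False):
        times = vkey[(row.user_id, row.facility_id)]
        t = row.entry_time
        prior = times[(times < t) & (times >= t - look_back)]
        if len(prior) == 0:
            ok_users.add(row.user_id)
    converted[converted.index.isin(ok_users)] = 1
    return converted


def local_show_conversion_rate(scored: pd.DataFrame, T: int) -> pd.DataFrame:
    """Local show conversion rate per user and the percentile curve.

    ``scored`` needs columns ``user_id``, ``score`` (in [0, 1]) and
    ``converted`` (0/1).  Users are ranked by score (ties broken by user
    id for determinism); the local rate at rank r is the mean converted
    flag over the T-person window centered at r, truncated at the ends of
    the ranking.  The returned frame adds ``rank``, ``percentile``
    (normalized rank of increasing score) and ``local_rate``.
    """
    if len(scored) == 0:
        raise GeoseekError("empty scored population")
    df = scored.sort_values(["score", "user_id"], kind="mergesort").reset_index(drop=True)
    conv = df["converted"].to_numpy(dtype=float)
    n = len(conv)
    cum = np.concatenate([[0.0], np.cumsum(conv)])
    r = np.arange(n)
    if T >= n:
        # full-window limit: every local rate is the global conversion rate
        lo = np.zeros(n, dtype=int)
        hi = np.full(n, n - 1)
    else:
        half = T // 2
        lo = np.maximum(0, r - half)
        hi = np.minimum(n - 1, r + half)
    rate = (cum[hi + 1] - cum[lo]) / (hi - lo + 1)
    df["rank"] = r + 1
    df["percentile"] = (r + 0.5) / n
    df["local_rate"] = rate
    return df


def score_to_coefficient(score, lo: float = 0.7, hi: float = 1.3):
    """Map predicted scores in [0, 1] linearly onto bid coefficients.

    The default range reproduces the (0.7, 1.3) adjustment interval:
    coefficient = lo + (hi - lo) * score, monotone increasing with the
    endpoints attained at scores 0 and 1.  Any other monotone map onto the
    interval may be substituted upstream; the linear one is the simplest.
    """
    s = np.asarray(score, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise GeoseekError("scores must lie in [0, 1]")
    out = lo + (hi - lo) * s
    return float(out) if np.isscalar(score) else out


def ab_metrics(group_a: pd.DataFrame, group_b: pd.DataFrame) -> dict:
    """Relative A/B changes in show conversion rate and CPA.

    Each group frame has one row per impression with ``converted`` (0/1,
    whether that impression led to a conversion) and ``cost``.  Show
    conversion rate = conversions / impressions; CPA = total cost /
    conversions.  Reported numbers are 100 * (B - A) / A; a group with
    zero conversions yields an undefined CPA and sets ``cpa_defined`` to
    False.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise GeoseekError("both A/B groups need impressions")

    def _grp(g):
        conv = float(g["converted"].sum())
        rate = conv / len(g)
        cpa = float(g["cost"].sum()) / conv if conv > 0 else np.nan
        return conv, rate, cpa

    conv_a, rate_a, cpa_a = _grp(group_a)
    conv_b, rate_b, cpa_b = _grp(group_b)
    cpa_defined = conv_a > 0 and conv_b > 0
    out = {
        "show_conversion_rate_a": rate_a,
        "show_conversion_rate_b": rate_b,
        "show_conversion_change_pct": 100.0 * (rate_b - rate_a) / rate_a
        if rate_a > 0 else np.nan,
        "cpa_a": cpa_a,
        "cpa_b": cpa_b,
        "cpa_change_pct": 100.0 * (cpa_b - cpa_a) / cpa_a if cpa_defined else np.nan,
        "cpa_defined": cpa_defined,
    }
    return out
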