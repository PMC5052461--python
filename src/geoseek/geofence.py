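"""Geofence visit detection, cohort filters, control matching, windows.

A putative medical-facility visit is inferred purely from log geometry: a
contiguous run of one user's searches inside the 200 m geofence of the same
facility, whose first-to-last timestamp span (the dwell time) is at least
900 s.  Users with a retained visit become patient candidates; three
exclusion filters remove probable staff/residents, and the remaining users
must have at least 42 distinct search days before their first visit.
Controls are users with no retained visit, matched to patients on the
number of available search days.

Each cohort member is then partitioned into an analysis window of exactly
41 *search days* (calendar dates with at least one search) preceding an
endpoint — the first visit date for patients, a seeded random date for
controls — with the endpoint day itself excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DAY_S, GeofencePolicy
from .errors import ControlPoolError, GeoseekError, InsufficientHistoryError

RECORD_COLUMNS = ["user_id", "ts", "lat", "lon", "tokens"]


# ---------------------------------------------------------------------------
# distance


def haversine_distance(lat1, lon1, lat2, lon2, earth_radius_m: float = 6_371_000.0):
    """Great-circle distance in meters between points in decimal degrees.

    Vectorized over numpy arrays; symmetric and nonnegative.  One degree of
    latitude is ~111 km on the default sphere, so 1e-4 degrees is ~11 m —
    the precision retained when coordinates are rounded to four decimals.
    """
    lat1, lon1, lat2, lon2 = (np.asarray(x, dtype=float) for x in (lat1, lon1, lat2, lon2))
    for lat in (lat1, lat2):
        if np.any(np.abs(lat) > 90):
            raise ValueError("latitude outside [-90, 90]")
    for lon in (lon1, lon2):
        if np.any(np.abs(lon) > 180):
            raise ValueError("longitude outside [-180, 180]")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * earth_radius_m * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def nearest_facility(records: pd.DataFrame, facilities: pd.DataFrame,
                     policy: GeofencePolicy) -> pd.DataFrame:
    """Per record: nearest facility id and distance; NaN/<NA> outside all fences.

    Returns a DataFrame aligned with ``records`` with columns
    ``facility_id`` (nullable string, only set when within ``radius_m``)
    and ``facility_dist_m``.
    """
    if len(facilities) == 0:
        raise GeoseekError("facility list is empty")
    flat = facilities["lat"].to_numpy()
    flon = facilities["lon"].to_numpy()
    fids = facilities["facility_id"].to_numpy()
    rlat = records["lat"].to_numpy()
    rlon = records["lon"].to_numpy()
    n = len(records)
    best_d = np.full(n, np.inf)
    best_i = np.zeros(n, dtype=int)
    # chunked over records to bound the n_records x n_facilities matrix
    chunk = max(1, 20_000_000 // max(len(facilities), 1))
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        d = haversine_distance(
            rlat[sl, None], rlon[sl, None], flat[None, :], flon[None, :],
            policy.earth_radius_m,
        )
        best_i[sl] = np.argmin(d, axis=1)
        best_d[sl] = d[np.arange(d.shape[0]), best_i[sl]]
    infence = best_d <= policy.radius_m
    out = pd.DataFrame(index=records.index)
    out["facility_id"] = pd.array(
        np.where(infence, fids[best_i], None), dtype="object")
    out["facility_dist_m"] = best_d
    return out


# ---------------------------------------------------------------------------
# visit detection


def detect_facility_visits(records: pd.DataFrame, facilities: pd.DataFrame,
                           policy: GeofencePolicy) -> pd.DataFrame:
    """Detect facility visits from contiguous in-fence search runs.

    A candidate run is a maximal sequence of one user's time-ordered searches
    all within ``radius_m`` of the same facility, not interrupted by an
    out-of-fence search and with no more than ``run_gap_s`` between
    consecutive members (a gap cap prevents day-spanning phantom dwells).
    The dwell time is last minus first timestamp of the run; runs shorter
    than ``min_dwell_s`` are discarded.

    Returns a DataFrame with columns user_id, facility_id, entry_time,
    dwell_s, n_searches_in_fence, sorted by (user_id, entry_time).
    """
    recs = records.sort_values(["user_id", "ts"], kind="mergesort").reset_index(drop=True)
    fence = nearest_facility(recs, facilities, policy)
    fid = fence["facility_id"].to_numpy(dtype=object)
    uid = recs["user_id"].to_numpy()
    ts = recs["ts"].to_numpy(dtype=np.int64)

    infence = np.array([f is not None for f in fid])
    same_user = np.concatenate([[False], uid[1:] == uid[:-1]])
    same_fac = np.concatenate(
        [[False], (fid[1:] == fid[:-1]) & infence[1:] & infence[:-1]])
    small_gap = np.concatenate([[False], (ts[1:] - ts[:-1]) <= policy.run_gap_s])
    # a record continues the previous run iff same user, same fence, small gap
    cont = same_user & same_fac & small_gap
    run_id = np.cumsum(~cont)

    df = pd.DataFrame({
        "run": run_id[infence],
        "user_id": uid[infence],
        "facility_id": fid[infence],
        "ts": ts[infence],
    })
    if df.empty:
        return pd.DataFrame(columns=["user_id", "facility_id", "entry_time",
                                     "dwell_s", "n_searches_in_fence"])
    g = df.groupby("run", sort=True)
    events = pd.DataFrame({
        "user_id": g["user_id"].first(),
        "facility_id": g["facility_id"].first(),
        "entry_time": g["ts"].min(),
        "dwell_s": (g["ts"].max() - g["ts"].min()).astype(float),
        "n_searches_in_fence": g["ts"].size(),
    }).reset_index(drop=True)
    events = events[events["dwell_s"] >= policy.min_dwell_s]
    return events.sort_values(["user_id", "entry_time"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# calendar helpers


def day_index(ts, tz_offset_s: int = 0):
    """Local calendar date as integer days since epoch."""
    return (np.asarray(ts, dtype=np.int64) + tz_offset_s) // DAY_S


def month_key(ts, tz_offset_s: int = 0):
    """Local calendar month as integer (year*12 + month)."""
    days = day_index(ts, tz_offset_s)
    dates = pd.to_datetime(days * DAY_S, unit="s")
    return dates.year * 12 + dates.month


def search_days(records: pd.DataFrame, tz_offset_s: int = 0) -> pd.Series:
    """Per user: number of distinct local dates with at least one search."""
    d = day_index(records["ts"].to_numpy(), tz_offset_s)
    return pd.Series(d).groupby(records["user_id"].to_numpy()).nunique()


# ---------------------------------------------------------------------------
# cohort filters


def apply_cohort_filters(records: pd.DataFrame, visits: pd.DataFrame,
                         facilities: pd.DataFrame,
                         policy: GeofencePolicy) -> pd.DataFrame:
    """Apply the inclusion/exclusion filters; return the patient table.

    Retained patients satisfy all of:

    1. at least one retained visit event (dwell >= 900 s);
    2. at most 15 facility-proximal searches in every calendar month
       (proximal = within the same 200 m radius used for detection);
    3. at most 5 distinct proximal facilities in every calendar month;
    4. at least 42 distinct search days strictly before the endpoint visit
       date (first visit by default; configurable to last).

    Filters 2 and 3 remove users who likely live or work near a facility
    (including health-care professionals).  The three exclusion predicates
    are conjunctive, hence order-independent.

    Returns a DataFrame (user_id, first_visit_time, endpoint_time,
    n_prior_search_days) for retained patients.
    """
    if visits.empty:
        return pd.DataFrame(columns=["user_id", "first_visit_time",
                                     "endpoint_time", "n_prior_search_days"])
    fence = nearest_facility(records, facilities, policy)
    proximal = fence["facility_id"].notna().to_numpy()
    prox = pd.DataFrame({
        "user_id": records["user_id"].to_numpy()[proximal],
        "facility_id": fence["facility_id"].to_numpy()[proximal],
        "month": month_key(records["ts"].to_numpy()[proximal], policy.tz_offset_s),
    })

    monthly_counts = prox.groupby(["user_id", "month"]).size()
    too_many_searches = set(
        monthly_counts[monthly_counts > policy.max_monthly_proximal_searches]
        .index.get_level_values("user_id"))
    monthly_fac = prox.groupby(["user_id", "month"])["facility_id"].nunique()
    too_many_facilities = set(
        monthly_fac[monthly_fac > policy.max_monthly_distinct_facilities]
        .index.get_level_values("user_id"))

    agg = "min" if policy.endpoint == "first" else "max"
    endpoint_visit = visits.groupby("user_id")["entry_time"].agg(agg)
    first_visit = visits.groupby("user_id")["entry_time"].min()

    rows = []
    rec_uid = records["user_id"].to_numpy()
    rec_day = day_index(records["ts"].to_numpy(), policy.tz_offset_s)
    day_series = pd.Series(rec_day).groupby(rec_uid)
    days_per_user = {u: np.unique(d.to_numpy()) for u, d in day_series}
    for user, ep_time in endpoint_visit.items():
        if user in too_many_searches or user in too_many_facilities:
            continue
        ep_day = int(day_index(ep_time, policy.tz_offset_s))
        n_prior = int((days_per_user[user] < ep_day).sum())
        if n_prior < policy.min_history_days:
            continue
        rows.append((user, int(first_visit[user]), int(ep_time), n_prior))
    return pd.DataFrame(rows, columns=["user_id", "first_visit_time",
                                       "endpoint_time", "n_prior_search_days"])


def sample_controls(records: pd.DataFrame, patients: pd.DataFrame,
                    visits: pd.DataFrame, policy: GeofencePolicy,
                    seed: int) -> pd.DataFrame:
    """Draw one control per patient, matched on search-day count.

    The candidate pool is every user with no retained visit event.  For each
    patient (in seeded random order) a pool user with an identical number of
    distinct search days is drawn when available; otherwise the nearest
    available count is used and flagged (``exact_match = False``).

    Raises :class:`ControlPoolError` when the pool is smaller than the
    number of patients.
    """
    visited = set(visits["user_id"].unique()) if not visits.empty else set()
    all_users = pd.Index(records["user_id"].unique())
    pool = [u for u in all_users if u not in visited]
    if len(pool) < len(patients):
        raise ControlPoolError(len(pool), len(patients))

    sd = search_days(records, policy.tz_offset_s)
    rng = np.random.default_rng(seed)
    pool = sorted(pool)
    rng.shuffle(pool)
    pool_days = np.array([sd[u] for u in pool])
    available = np.ones(len(pool), dtype=bool)

    patient_order = patients.sort_values("user_id").reset_index(drop=True)
    order = rng.permutation(len(patient_order))
    rows = []
    for i in order:
        p = patient_order.iloc[i]
        target = sd[p["user_id"]]
        cand = np.flatnonzero(available)
        gaps = np.abs(pool_days[cand] - target)
        j = cand[int(np.argmin(gaps))]
        available[j] = False
        rows.append((pool[j], p["user_id"], int(pool_days[j]),
                     bool(pool_days[j] == target)))
    out = pd.DataFrame(rows, columns=["user_id", "matched_patient",
                                      "n_search_days", "exact_match"])
    return out.sort_values("user_id").reset_index(drop=True)


# ---------------------------------------------------------------------------
# analysis windows


@dataclass
class AnalysisWindow:
    """A user's searches bucketed into 41 search days before an endpoint.

    ``records`` carries a ``day_bucket`` column with values 1..n_days where
    bucket 1 is the search day nearest the endpoint.  No record is at or
    after ``endpoint_time`` (the start of the endpoint's local date).
    """

    user_id: str
    label: str  # "patient" | "control"
    endpoint_time: int
    records: pd.DataFrame
    n_days: int = 41

    def day(self, bucket: int) -> pd.DataFrame:
        return self.records[self.records["day_bucket"] == bucket]


def partition_window(user_records: pd.DataFrame, endpoint_time: int, label: str,
                     policy: GeofencePolicy, n_days: int = 41) -> AnalysisWindow:
    """Bucket one user's log into the ``n_days`` search days before an endpoint.

    ``endpoint_time`` is any timestamp on the endpoint date (for patients,
    the first visit's entry time).  The endpoint date itself is excluded;
    day buckets count *search days* (dates with >= 1 search) backward from
    the endpoint, bucket 1 being the most recent.

    Raises :class:`InsufficientHistoryError` with the qualifying-day count
    when fewer than ``n_days`` search days precede the endpoint.
    """
    uid = user_records["user_id"].iloc[0]
    ep_day = int(day_index(endpoint_time, policy.tz_offset_s))
    days = day_index(user_records["ts"].to_numpy(), policy.tz_offset_s)
    before = days < ep_day
    uniq = np.unique(days[before])
    if len(uniq) < n_days:
        raise InsufficientHistoryError(uid, len(uniq), n_days)
    kept_days = uniq[-n_days:]
    bucket_of = {d: n_days - i for i, d in enumerate(kept_days)}
    mask = before & np.isin(days, kept_days)
    recs = user_records.loc[mask].copy()
    recs["day_bucket"] = [bucket_of[d] for d in days[mask]]
    recs = recs.sort_values("ts", kind="mergesort").reset_index(drop=True)
    endpoint_start = ep_day * DAY_S - policy.tz_offset_s
    return AnalysisWindow(user_id=uid, label=label, endpoint_time=endpoint_start,
                          records=recs, n_days=n_days)


def choose_control_endpoint(user_records: pd.DataFrame, policy: GeofencePolicy,
                            rng: np.random.Generator, n_days: int = 41) -> int:
    """Seeded random endpoint date for a control user.

    Picked uniformly among the user's search days that have at least
    ``n_days`` earlier search days, so the window is always constructible.
    Returns a timestamp at the start of the chosen local date.
    """
    days = np.unique(day_index(user_records["ts"].to_numpy(), policy.tz_offset_s))
    if len(days) < n_days + 1:
        uid = user_records["user_id"].iloc[0]
        raise InsufficientHistoryError(uid, max(len(days) - 1, 0), n_days)
    eligible = days[n_days:]
    chosen = int(eligible[rng.integers(len(eligible))])
    return chosen * DAY_S - policy.tz_offset_s


def build_windows(records: pd.DataFrame, patients: pd.DataFrame,
                  controls: pd.DataFrame, policy: GeofencePolicy,
                  seed: int, n_days: int = 41) -> list[AnalysisWindow]:
    """Partition every cohort member; skips nobody silently.

    Patients use their endpoint visit date; controls get seeded random
    endpoints.  Users failing the history requirement raise — the cohort
    filters should have removed them already.
    """
    rng = np.random.default_rng(seed)
    by_user = dict(tuple(records.groupby("user_id", sort=True)))
    windows = []
    for _, p in patients.sort_values("user_id").iterrows():
        windows.append(partition_window(by_user[p["user_id"]],
                                        int(p["endpoint_time"]), "patient",
                                        policy, n_days))
    for _, c in controls.sort_values("user_id").iterrows():
        urecs = by_user[c["user_id"]]
        ep = choose_control_endpoint(urecs, policy, rng, n_days)
        # endpoint is a day start; pass a time on that date
        windows.append(partition_window(urecs, ep, "control", policy, n_days))
    return windows
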