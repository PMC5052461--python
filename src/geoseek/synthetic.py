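"""Seeded synthetic worlds and user search-log streams.

The generator emulates, at desk scale, the statistical structure the
analysis assumes in mobile search logs: a map with medical facilities and
a landmark gazetteer, a toy medical lexicon with ontology structure, and
per-user daily search streams.  Patients carry a planted escalation in the
final ``signal_onset_day`` days before a facility visit — health-search
volume rises, intervals between health searches shorten, searched terms
drift toward high information content, and searches increasingly originate
near health-category landmarks — ending in a geofence dwell of >= 900 s at
one facility.  Controls emit stationary baseline streams and never enter
any facility geofence.  Outside the escalation window the two classes are
generated by the identical process, so features restricted to earlier days
carry no class signal.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (AdStreamConfig, CohortConfig, DAY_S, SEMANTIC_GROUPS,
                     VISIT_TYPES, WorldConfig)
from .errors import ConfigError, GeoseekError
from .geofence import haversine_distance
from .lexicon import ROOT, Lexicon

_CATEGORY_POOL = ["health", "restaurant", "education", "shopping",
                  "accommodation", "transport", "park", "office",
                  "entertainment", "sports"]

_CATEGORY_WORDS = {
    "health": ["clinic", "pharmacy", "infirmary"],
    "restaurant": ["diner", "noodle", "grill"],
    "education": ["elementary", "university", "academy"],
    "shopping": ["mall", "market", "plaza"],
    "accommodation": ["hotel", "inn", "hostel"],
    "transport": ["station", "terminal", "depot"],
    "park": ["garden", "grove", "commons"],
    "office": ["tower", "bureau", "center"],
    "entertainment": ["cinema", "arcade", "theater"],
    "sports": ["stadium", "gym", "arena"],
}

_NAME_PREFIXES = ["north", "south", "east", "west", "central", "city",
                  "river", "golden", "spring", "lake"]

#: degrees of latitude per meter on the default sphere (~1/111 km)
_DEG_PER_M = 1.0 / 111_195.0

_SAFE_DISTANCE_M = 500.0  # landmarks/homes at least this far from any facility


@dataclass
class World:
    """Static synthetic geography and vocabulary."""

    facilities: pd.DataFrame   # facility_id, lat, lon, name
    landmarks: pd.DataFrame    # landmark_id, lat, lon, category, name
    lexicon: Lexicon
    term_truth: dict[str, bool]   # ground-truth health/non-health per term
    filler_tokens: list[str]
    filler_weights: np.ndarray
    config: WorldConfig


def _build_lexicon(rng: np.random.Generator, cfg: WorldConfig
                   ) -> tuple[Lexicon, dict[str, bool]]:
    """Grow a rooted concept DAG with monotone-frequency edges.

    Each semantic group gets a top-level concept under the root carrying a
    broad, frequent term; further concepts attach beneath an existing
    concept of the same group with a corpus frequency drawn as a fraction
    of the parent's, which enforces ancestor >= descendant frequency along
    every edge.  A small share of drug concepts also carries the procedure
    group (multi-group membership), and a few concepts receive a second
    parent, making the hierarchy a genuine DAG.
    """
    group_share = {"disease": 0.35, "drug": 0.30, "procedure": 0.20, "device": 0.15}
    n_terms = cfg.lexicon_size
    term_concepts: dict[str, tuple[str, ...]] = {}
    concept_parents: dict[str, tuple[str, ...]] = {}
    concept_groups: dict[str, tuple[str, ...]] = {}
    term_freq: dict[str, int] = {}
    freq_of: dict[str, int] = {}
    by_group: dict[str, list[str]] = {g: [] for g in SEMANTIC_GROUPS}

    counts = {g: max(2, int(round(share * n_terms)))
              for g, share in group_share.items()}
    # trim/pad to hit lexicon_size exactly
    while sum(counts.values()) > n_terms:
        counts[max(counts, key=counts.get)] -= 1
    while sum(counts.values()) < n_terms:
        counts["disease"] += 1

    for g in SEMANTIC_GROUPS:
        top = f"C_{g}_top"
        concept_parents[top] = (ROOT,)
        concept_groups[top] = (g,)
        term = f"{g}_general"
        term_concepts[term] = (top,)
        freq_of[top] = 4000
        term_freq[term] = 4000
        by_group[g].append(top)
        for i in range(counts[g] - 1):
            cid = f"C_{g}_{i:03d}"
            parent = by_group[g][int(rng.integers(len(by_group[g])))]
            freq = max(1, int(freq_of[parent] * rng.uniform(0.15, 0.7)))
            parents = [parent]
            # occasional second parent (DAG, not a tree); must respect the
            # frequency invariant, so only richer concepts qualify
            if rng.random() < 0.05:
                rich = [c for c in by_group[g] if freq_of[c] >= freq and c != parent]
                if rich:
                    parents.append(rich[int(rng.integers(len(rich)))])
            groups = (g,)
            if g == "drug" and rng.random() < 0.08:
                groups = ("drug", "procedure")
            concept_parents[cid] = tuple(parents)
            concept_groups[cid] = groups
            term = f"{g}_{i:03d}"
            term_concepts[term] = (cid,)
            term_freq[term] = freq
            freq_of[cid] = freq
            by_group[g].append(cid)

    lex = Lexicon(term_concepts=term_concepts, concept_parents=concept_parents,
                  concept_groups=concept_groups, term_freq=term_freq)
    truth: dict[str, bool] = {}
    for term in term_concepts:
        groups = lex.term_semantic_groups(term)
        if groups == {"device"}:
            truth[term] = bool(rng.random() >= cfg.device_noise_rate)
        else:
            truth[term] = True
    return lex, truth


def generate_world(config: WorldConfig) -> World:
    """Generate facilities, landmark gazetteer, toy lexicon, and term truth.

    Facilities and landmarks are placed uniformly in ``map_extent``; the
    landmark category set always includes ``health``.  With
    ``device_noise_rate = 0`` every device-mapped term is truly
    health-related; at rate r a fraction r of device terms is secretly
    non-medical, planting the misattribution the agreement experiment
    measures.  Identical seeds give byte-identical worlds.
    """
    rng = np.random.default_rng(config.seed)
    lat0, lon0, lat1, lon1 = config.map_extent

    def uniform_points(n):
        return (rng.uniform(lat0, lat1, n), rng.uniform(lon0, lon1, n))

    flat, flon = uniform_points(config.n_facilities)
    facilities = pd.DataFrame({
        "facility_id": [f"F{i:04d}" for i in range(config.n_facilities)],
        "lat": flat, "lon": flon,
        "name": [f"{_NAME_PREFIXES[i % len(_NAME_PREFIXES)]} hospital"
                 for i in range(config.n_facilities)],
    })

    cats = _CATEGORY_POOL[: config.n_landmark_categories]
    llat, llon = uniform_points(config.n_landmarks)
    cat_choice = [cats[int(rng.integers(len(cats)))] for _ in range(config.n_landmarks)]
    names = []
    for c in cat_choice:
        words = _CATEGORY_WORDS.get(c, ["place"])
        names.append(f"{_NAME_PREFIXES[int(rng.integers(len(_NAME_PREFIXES)))]} "
                     f"{words[int(rng.integers(len(words)))]}")
    landmarks = pd.DataFrame({
        "landmark_id": [f"L{i:05d}" for i in range(config.n_landmarks)],
        "lat": llat, "lon": llon, "category": cat_choice, "name": names,
    })

    lexicon, truth = _build_lexicon(rng, config)
    filler = [f"w{i:04d}" for i in range(config.n_filler_tokens)]
    zipf = 1.0 / np.arange(1, config.n_filler_tokens + 1) ** 1.1
    return World(facilities=facilities, landmarks=landmarks, lexicon=lexicon,
                 term_truth=truth, filler_tokens=filler,
                 filler_weights=zipf / zipf.sum(), config=config)


# ---------------------------------------------------------------------------
# user streams


def _safe_mask(landmarks: pd.DataFrame, facilities: pd.DataFrame) -> np.ndarray:
    d = haversine_distance(
        landmarks["lat"].to_numpy()[:, None], landmarks["lon"].to_numpy()[:, None],
        facilities["lat"].to_numpy()[None, :], facilities["lon"].to_numpy()[None, :])
    return d.min(axis=1) >= _SAFE_DISTANCE_M


def _sample_home(rng, extent, facilities) -> tuple[float, float]:
    lat0, lon0, lat1, lon1 = extent
    for _ in range(200):
        la = rng.uniform(lat0, lat1)
        lo = rng.uniform(lon0, lon1)
        d = haversine_distance(la, lo, facilities["lat"].to_numpy(),
                               facilities["lon"].to_numpy())
        if d.min() >= _SAFE_DISTANCE_M:
            return la, lo
    raise GeoseekError("could not place a home away from all facilities")


def _jitter(rng, lat, lon, sigma_m: float, cap_m: float = 250.0):
    dx = np.clip(rng.normal(0, sigma_m), -cap_m, cap_m)
    dy = np.clip(rng.normal(0, sigma_m), -cap_m, cap_m)
    dlat = dx * _DEG_PER_M
    dlon = dy * _DEG_PER_M / max(math.cos(math.radians(lat)), 0.2)
    return lat + dlat, lon + dlon


def _shrinking_times(rng, n: int, day_start: int, shrink: float) -> np.ndarray:
    """A burst of n timestamps whose successive intervals contract by 1/shrink."""
    start = day_start + rng.uniform(8 * 3600, 16 * 3600)
    delta0 = rng.uniform(900, 1800)
    times = [start]
    d = delta0
    for _ in range(n - 1):
        times.append(times[-1] + d)
        d /= shrink
    return np.array(times)


def generate_users(world: World, config: CohortConfig
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate per-user search streams plus the ground-truth table.

    Patients (``P####``) and controls (``C####``) share the baseline
    process: per-day search counts are Poisson around
    ``baseline_searches_per_day`` with a fraction ``health_search_prob``
    of searches carrying a lexicon term, searches placed at the user's
    home (occasionally at a landmark).  In a patient's final
    ``signal_onset_day`` days each planted signal ramps linearly from the
    baseline to its full effect size, scaled by the user's latent risk;
    the stream ends in a >= 900 s dwell inside one facility geofence on
    the last day.  Controls never come within the safe distance of a
    facility.

    Returns ``(records, ground_truth)``; records have columns
    user_id, ts, lat, lon, tokens (tuple of strings).
    """
    if config.days_per_user < 42:
        raise ConfigError("days_per_user must be >= 42")
    rng = np.random.default_rng(config.seed)
    lex = world.lexicon
    eff = config.effect_sizes

    health_terms = sorted(lex.terms_in_groups(SEMANTIC_GROUPS))
    base_w = np.array([lex.term_freq[t] for t in health_terms], dtype=float)
    base_w /= base_w.sum()
    ic = np.array([min(lex.information_content(t), 50.0) for t in health_terms])

    # specialty pools: disjoint quarters of the health terms (seeded); each
    # visit type also gets a small high-IC "signature" subset — the specific
    # condition terms its patients converge on while escalating
    pool_idx = rng.permutation(len(health_terms))
    pools = {vt: set(np.array(health_terms)[pool_idx[k::4]])
             for k, vt in enumerate(VISIT_TYPES)}
    pool_masks = {vt: np.array([t in pools[vt] for t in health_terms])
                  for vt in VISIT_TYPES}
    signatures = {}
    for vt in VISIT_TYPES:
        members = sorted(pools[vt], key=lambda t: (-lex.information_content(t), t))
        signatures[vt] = [t for t in members if math.isfinite(
            lex.information_content(t))][:6]

    safe = _safe_mask(world.landmarks, world.facilities)
    safe_lm = world.landmarks[safe].reset_index(drop=True)
    safe_health = safe_lm[safe_lm["category"] == "health"].reset_index(drop=True)
    if len(safe_health) == 0:
        raise GeoseekError("no health-category landmark away from facilities")

    t0 = config.start_time
    onset = config.signal_onset_day
    visit_day = config.days_per_user - 1

    rows_uid, rows_ts, rows_lat, rows_lon, rows_tok = [], [], [], [], []
    gt_rows = []

    def emit(uid, ts, la, lo, toks):
        rows_uid.append(uid)
        rows_ts.append(int(ts))
        rows_lat.append(la)
        rows_lon.append(lo)
        rows_tok.append(tuple(toks))

    # terms the lexicon wrongly maps to medical concepts are ordinary words,
    # so they show up in everyday searches of every user
    noisy_terms = sorted(t for t, ok in world.term_truth.items() if not ok)

    def sample_tokens(n_filler_mean=1.2):
        k = 1 + rng.poisson(n_filler_mean)
        idx = rng.choice(len(world.filler_tokens), size=k, p=world.filler_weights)
        toks = [world.filler_tokens[i] for i in idx]
        if noisy_terms and rng.random() < 0.10:
            toks.append(noisy_terms[int(rng.integers(len(noisy_terms)))])
        return toks

    def health_term_weights(phi, risk, visit_type):
        m_spec = 1.0 + phi * risk * (eff.specificity_drift - 1.0)
        w = base_w * np.power(m_spec, ic)
        if visit_type is not None and phi > 0:
            w = np.where(pool_masks[visit_type], w * 4.0, w)
        return w / w.sum()

    user_specs = [("patient", f"P{i:04d}") for i in range(config.n_patients)] + \
                 [("control", f"C{i:04d}") for i in range(config.n_controls)]

    for label, uid in user_specs:
        is_patient = label == "patient"
        risk = float(rng.beta(5, 2)) if is_patient else float(rng.beta(2, 5))
        home = _sample_home(rng, world.config.map_extent, world.facilities)
        visit_type = VISIT_TYPES[int(rng.integers(4))] if is_patient else None
        facility = world.facilities.iloc[int(rng.integers(len(world.facilities)))] \
            if is_patient else None
        first_visit_time = None

        for d in range(config.days_per_user):
            day_start = t0 + d * DAY_S
            escalated = is_patient and (visit_day - onset) <= d < visit_day
            phi = (d - (visit_day - onset) + 1) / onset if escalated else 0.0

            m_rate = 1.0 + phi * risk * (eff.health_rate - 1.0)
            m_int = 1.0 + phi * risk * (eff.interval_shortening - 1.0)
            m_loc = 1.0 + phi * risk * (eff.location_rate - 1.0)

            n_nh = rng.poisson(config.baseline_searches_per_day
                               * (1.0 - config.health_search_prob))
            n_h = rng.poisson(config.baseline_searches_per_day
                              * config.health_search_prob * m_rate)

            # on the visit day background searches stay before the 10:00
            # facility dwell so they cannot interrupt the in-fence run
            hi = 9.5 * 3600 if (is_patient and d == visit_day) else 23 * 3600
            nh_times = day_start + rng.uniform(8 * 3600, hi, n_nh)
            if n_h >= 3 and m_int > 1.001:
                h_times = _shrinking_times(rng, n_h, day_start, m_int)
            else:
                h_times = day_start + rng.uniform(8 * 3600, hi, n_h)

            if n_h > 0:
                hw = health_term_weights(phi, risk, visit_type)
            p_health_lm = min(0.8, 0.05 * m_loc)
            for ts, is_h in sorted(
                    [(t, False) for t in nh_times] + [(t, True) for t in h_times]):
                r = rng.random()
                if r < p_health_lm:
                    lm = safe_health.iloc[int(rng.integers(len(safe_health)))]
                    la, lo = _jitter(rng, lm["lat"], lm["lon"], 20.0, 40.0)
                elif r < p_health_lm + 0.15:
                    lm = safe_lm.iloc[int(rng.integers(len(safe_lm)))]
                    la, lo = _jitter(rng, lm["lat"], lm["lon"], 20.0, 40.0)
                else:
                    la, lo = _jitter(rng, home[0], home[1], 80.0)
                toks = sample_tokens()
                if is_h:
                    # escalating patients increasingly repeat their specific
                    # condition (signature) terms; the mixing weight vanishes
                    # when the specificity-drift effect is null
                    m_spec = 1.0 + phi * risk * (eff.specificity_drift - 1.0)
                    sig_p = 0.8 * (1.0 - 1.0 / m_spec)
                    if visit_type is not None and rng.random() < sig_p:
                        sig = signatures[visit_type]
                        term = sig[int(rng.integers(len(sig)))]
                    else:
                        term = health_terms[int(rng.choice(len(health_terms), p=hw))]
                    toks.append(term)
                emit(uid, ts, la, lo, toks)

            if is_patient and d == visit_day:
                base = day_start + 10 * 3600
                for k, off in enumerate((0, 500, 1000)):
                    la, lo = _jitter(rng, facility["lat"], facility["lon"], 15.0, 30.0)
                    toks = sample_tokens()
                    if k == 0:
                        toks.append(
                            health_terms[int(rng.choice(len(health_terms), p=base_w))])
                    emit(uid, base + off, la, lo, toks)
                first_visit_time = int(base)

        gt_rows.append({
            "user_id": uid, "label": label, "latent_risk": risk,
            "first_visit_time": first_visit_time,
            "visit_type": visit_type,
        })

    records = pd.DataFrame({
        "user_id": rows_uid, "ts": rows_ts, "lat": rows_lat,
        "lon": rows_lon, "tokens": rows_tok,
    }).sort_values(["user_id", "ts"], kind="mergesort").reset_index(drop=True)
    ground_truth = pd.DataFrame(gt_rows)
    return records, ground_truth


# ---------------------------------------------------------------------------
# ad impressions


def generate_ad_stream(ground_truth: pd.DataFrame, facilities: pd.DataFrame,
                       config: AdStreamConfig,
                       show_weight: dict[str, float] | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic ad impressions plus the visits they trigger.

    Each user receives Poisson(``impressions_per_user``) impressions from
    random facilities with lognormal costs.  The probability that a visit
    to the advertised facility follows within ``lookahead_days`` is the
    increasing function ``base_conversion_rate + risk_slope * latent_risk``
    of the user's latent risk; a converting user's visit is emitted as a
    visit event so that conversion labeling can recover it.  An optional
    ``show_weight`` multiplies a user's impression rate (used to emulate
    bid-coefficient targeting in the treated A/B arm).

    Returns ``(impressions, visits)``; an empty request yields empty,
    well-formed frames.
    """
    rng = np.random.default_rng(config.seed)
    t_show0 = 1_433_116_800  # 2015-06-01T00:00:00Z
    imp_rows, visit_rows = [], []
    for row in ground_truth.sort_values("user_id").itertuples(index=False):
        w = 1.0 if show_weight is None else float(show_weight.get(row.user_id, 1.0))
        n_imp = rng.poisson(config.impressions_per_user * w)
        if n_imp == 0:
            continue
        shown = np.sort(t_show0 + rng.uniform(0, 7 * DAY_S, n_imp)).astype(int)
        fac = [facilities["facility_id"].iloc[int(rng.integers(len(facilities)))]
               for _ in range(n_imp)]
        costs = np.exp(rng.normal(config.cost_mu, config.cost_sigma, n_imp))
        for t, f, c in zip(shown, fac, costs):
            imp_rows.append((row.user_id, f, int(t), float(c)))
        p = min(1.0, config.base_conversion_rate
                + config.risk_slope * float(row.latent_risk))
        if rng.random() < p:
            j = 0  # the first impression is the one acted upon
            delay = rng.uniform(1, config.lookahead_days - 1) * DAY_S
            visit_rows.append((row.user_id, fac[j], int(shown[j] + delay),
                               1000.0, 3))
    impressions = pd.DataFrame(
        imp_rows, columns=["user_id", "facility_id", "shown_time", "cost"])
    visits = pd.DataFrame(
        visit_rows,
        columns=["user_id", "facility_id", "entry_time", "dwell_s",
                 "n_searches_in_fence"])
    return impressions, visits
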