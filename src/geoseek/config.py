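"""Configuration objects for every pipeline stage.

Each stage of the pipeline (synthetic world/cohort generation, geofence
cohort construction, feature engineering, model fitting, ad evaluation) is
driven by a small frozen dataclass.  A :class:`RunConfig` nests one of each
and round-trips losslessly through YAML/JSON, so a whole run is reproducible
from a single file plus a global seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import yaml

from .errors import ConfigError

SEMANTIC_GROUPS = ("disease", "drug", "device", "procedure")
#: groups whose membership flags a search as health-care related; the device
#: group is excluded because device-term mappings are the noisiest.
HEALTH_GROUPS = ("disease", "drug", "procedure")

VISIT_TYPES = ("male", "female", "beauty", "other")

DAY_S = 86_400


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass(frozen=True)
class WorldConfig:
    """Static synthetic world: facilities, landmark gazetteer, toy lexicon."""

    n_facilities: int = 20
    n_landmarks: int = 200
    n_landmark_categories: int = 8
    map_extent: tuple[float, float, float, float] = (39.6, 116.0, 40.2, 116.8)
    lexicon_size: int = 200
    n_filler_tokens: int = 600
    device_noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_facilities > 0, "n_facilities must be positive")
        _require(self.n_landmarks > 0, "n_landmarks must be positive")
        _require(self.n_landmark_categories >= 2, "need at least 2 landmark categories")
        lat0, lon0, lat1, lon1 = self.map_extent
        _require(lat1 > lat0 and lon1 > lon0, "map_extent must have positive area")
        _require(-90 <= lat0 and lat1 <= 90 and -180 <= lon0 and lon1 <= 180,
                 "map_extent outside valid lat/lon ranges")
        _require(self.lexicon_size >= 20, "lexicon_size too small to build a DAG")
        _require(0.0 <= self.device_noise_rate <= 1.0,
                 "device_noise_rate must lie in [0, 1]")


@dataclass(frozen=True)
class EffectSizes:
    """Multiplicative strength of each planted pre-visit signal.

    All four default to values > 1 so that the planted escalation is visible
    to every feature category; ``1.0`` everywhere is the null world.
    """

    health_rate: float = 2.5       # health-search volume multiplier at the endpoint
    interval_shortening: float = 2.0  # successive-interval contraction factor
    specificity_drift: float = 1.5    # pull toward high-information-content terms
    location_rate: float = 3.0        # odds multiplier for health-landmark visits

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            _require(getattr(self, f.name) > 0, f"effect size {f.name} must be > 0")

    @property
    def is_null(self) -> bool:
        return all(getattr(self, f.name) == 1.0 for f in dataclasses.fields(self))


@dataclass(frozen=True)
class CohortConfig:
    """Synthetic user streams with ground-truth patient/control status."""

    n_patients: int = 500
    n_controls: int = 500
    days_per_user: int = 60
    signal_onset_day: int = 15
    effect_sizes: EffectSizes = field(default_factory=EffectSizes)
    baseline_searches_per_day: float = 3.0
    health_search_prob: float = 0.15
    start_time: int = 1_425_168_000  # 2015-03-01T00:00:00Z
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_patients >= 0 and self.n_controls >= 0, "negative cohort size")
        _require(self.days_per_user >= 42,
                 "days_per_user must be >= 42 (cohort inclusion requires 42 prior days)")
        _require(self.signal_onset_day >= 1, "signal_onset_day must be >= 1")
        _require(self.baseline_searches_per_day > 0, "baseline rate must be > 0")
        _require(0 < self.health_search_prob < 1, "health_search_prob must be in (0,1)")


@dataclass(frozen=True)
class AdStreamConfig:
    """Synthetic ad impressions whose conversion odds rise with latent risk."""

    impressions_per_user: float = 1.0
    base_conversion_rate: float = 0.02
    risk_slope: float = 0.25  # P(visit within 14d) = base + slope * latent_risk
    cost_mu: float = 1.0      # lognormal cost parameters (currency units)
    cost_sigma: float = 0.5
    lookahead_days: int = 14
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.impressions_per_user >= 0, "impressions_per_user must be >= 0")
        _require(self.base_conversion_rate >= 0, "base_conversion_rate must be >= 0")
        _require(self.base_conversion_rate + max(self.risk_slope, 0.0) <= 1.0,
                 "conversion probability may exceed 1")


@dataclass(frozen=True)
class GeofencePolicy:
    """Thresholds for visit detection and the cohort inclusion filters."""

    radius_m: float = 200.0
    min_dwell_s: float = 900.0
    max_monthly_proximal_searches: int = 15
    max_monthly_distinct_facilities: int = 5
    min_history_days: int = 42
    earth_radius_m: float = 6_371_000.0
    run_gap_s: float = 21_600.0  # >6 h between in-fence searches breaks a run
    tz_offset_s: int = 0         # fixed offset defining local day boundaries
    endpoint: str = "first"      # "first" or "last" retained visit

    def __post_init__(self) -> None:
        for name in ("radius_m", "min_dwell_s", "max_monthly_proximal_searches",
                     "max_monthly_distinct_facilities", "min_history_days",
                     "earth_radius_m", "run_gap_s"):
            _require(getattr(self, name) > 0, f"{name} must be positive")
        _require(self.endpoint in ("first", "last"), "endpoint must be 'first' or 'last'")


@dataclass(frozen=True)
class FeatureConfig:
    """Knobs of the feature engine (Table-style daywise + aggregate features)."""

    irs_weight: float = 0.1
    irs_ratio_clamp: tuple[float, float] = (0.01, 100.0)
    session_gap_s: float = 1800.0
    n_enriched_tokens: int = 100
    n_enriched_location_categories: int = 53
    n_location_name_tokens: int = 113
    bonferroni_alpha: float = 0.05
    coord_round_places: int = 4
    n_window_days: int = 41
    specificity_mode: str = "max"  # "max" or "mean" of per-search maxima

    def __post_init__(self) -> None:
        _require(0 < self.irs_weight <= 1, "irs_weight must lie in (0, 1]")
        for name in ("session_gap_s", "n_enriched_tokens",
                     "n_enriched_location_categories", "n_location_name_tokens"):
            _require(getattr(self, name) > 0, f"{name} must be positive")
        _require(0 < self.bonferroni_alpha < 1, "bonferroni_alpha must be in (0,1)")
        _require(self.specificity_mode in ("max", "mean"),
                 "specificity_mode must be 'max' or 'mean'")


MODEL_FAMILIES = ("lasso", "ridge", "elastic_net", "svm_rbf", "random_forest")


@dataclass(frozen=True)
class ModelSpec:
    """A learner family plus its cross-validation protocol."""

    family: str = "random_forest"
    cv_folds: int = 5
    one_se_rule: bool = True
    n_lambdas: int = 50
    lambda_min_ratio: float = 1e-3
    enet_alphas: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9)
    svm_cost_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    n_trees: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.family in MODEL_FAMILIES,
                 f"family must be one of {MODEL_FAMILIES}")
        _require(self.cv_folds >= 2, "cv_folds must be >= 2")
        _require(self.n_lambdas >= 2, "n_lambdas must be >= 2")
        _require(self.n_trees >= 1, "n_trees must be >= 1")


@dataclass(frozen=True)
class ConversionPolicy:
    """Windows defining an ad conversion and the local-rate smoother width."""

    lookback_days: int = 30
    lookahead_days: int = 14
    window_T: int = 101

    def __post_init__(self) -> None:
        _require(self.lookback_days > 0, "lookback_days must be positive")
        _require(self.lookahead_days > 0, "lookahead_days must be positive")
        _require(self.window_T > 0, "window_T must be positive")


@dataclass(frozen=True)
class RunConfig:
    """One end-to-end run: nested stage configs plus a global seed."""

    world: WorldConfig = field(default_factory=WorldConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    ads: AdStreamConfig = field(default_factory=AdStreamConfig)
    geofence: GeofencePolicy = field(default_factory=GeofencePolicy)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    model: ModelSpec = field(default_factory=ModelSpec)
    conversion: ConversionPolicy = field(default_factory=ConversionPolicy)
    train_fraction: float = 0.8
    ablate: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        _require(0 < self.train_fraction < 1, "train_fraction must be in (0,1)")


# ---------------------------------------------------------------------------
# serialization


_NESTED: dict[str, type] = {
    "world": WorldConfig, "cohort": CohortConfig, "ads": AdStreamConfig,
    "geofence": GeofencePolicy, "features": FeatureConfig,
    "model": ModelSpec, "conversion": ConversionPolicy,
}


def to_dict(cfg: Any) -> dict:
    """Dataclass -> plain dict (tuples become lists)."""
    return json.loads(json.dumps(dataclasses.asdict(cfg)))


def _coerce(cls: type, data: dict) -> Any:
    kwargs = {}
    fields = {f.name: f for f in dataclasses.fields(cls)}
    for key, value in data.items():
        if key not in fields:
            raise ConfigError(f"unknown field {key!r} for {cls.__name__}")
        if key == "effect_sizes" and isinstance(value, dict):
            value = EffectSizes(**value)
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def run_config_from_dict(data: dict) -> RunConfig:
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key in _NESTED and isinstance(value, dict):
            kwargs[key] = _coerce(_NESTED[key], value)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def load_run_config(path: str) -> RunConfig:
    """Read a RunConfig from a YAML (or JSON; YAML is a superset) file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return run_config_from_dict(data)


def save_run_config(cfg: RunConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(cfg), fh, sort_keys=True)


def config_hash(cfg: Any) -> str:
    """Stable sha256 of a config's canonical JSON form."""
    blob = json.dumps(to_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def derive_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed from (global seed, stage name).

    Hash-derived so that changing how many random draws one stage makes can
    never perturb another stage's stream.  Result fits in 31 bits.
    """
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF
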