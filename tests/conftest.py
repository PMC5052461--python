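"""Shared fixtures: one small seeded synthetic study reused across tests."""

import pandas as pd
import pytest

import geoseek as gs
from geoseek.features import LandmarkResolver


SMALL_WORLD = gs.WorldConfig(seed=101, n_facilities=10, n_landmarks=80,
                             lexicon_size=120, n_filler_tokens=300)
SMALL_COHORT = gs.CohortConfig(n_patients=30, n_controls=40, seed=202)
SMALL_FEATURES = gs.FeatureConfig(n_enriched_tokens=20,
                                  n_enriched_location_categories=5,
                                  n_location_name_tokens=10)


@pytest.fixture(scope="session")
def world():
    return gs.generate_world(SMALL_WORLD)


@pytest.fixture(scope="session")
def cohort(world):
    """records, ground truth, detected visits, patients, controls, windows."""
    records, gt = gs.generate_users(world, SMALL_COHORT)
    policy = gs.GeofencePolicy()
    visits = gs.detect_facility_visits(records, world.facilities, policy)
    patients = gs.apply_cohort_filters(records, visits, world.facilities, policy)
    controls = gs.sample_controls(records, patients, visits, policy, seed=7)
    windows = gs.build_windows(records, patients, controls, policy, seed=8)
    return {"records": records, "ground_truth": gt, "visits": visits,
            "patients": patients, "controls": controls, "windows": windows,
            "policy": policy}


@pytest.fixture(scope="session")
def resolver(world):
    return LandmarkResolver(world.landmarks, SMALL_FEATURES)


@pytest.fixture(scope="session")
def matrices(world, cohort, resolver):
    selections = gs.fit_selections(cohort["windows"], resolver, SMALL_FEATURES)
    mats = gs.build_matrices(cohort["windows"], world.lexicon, resolver,
                             selections, SMALL_FEATURES)
    return mats, selections


@pytest.fixture()
def toy_lexicon():
    """Hand-built three-level lexicon with known frequencies.

    ROOT -> C_top (term 'broad', freq 999) -> C_leaf (term 'narrow', freq 1);
    aggregated root frequency is 1000, so IC('narrow') = ln(1000).
    """
    return gs.Lexicon(
        term_concepts={"broad": ("C_top",), "narrow": ("C_leaf",),
                       "dual": ("C_dual",)},
        concept_parents={"C_top": ("ROOT",), "C_leaf": ("C_top",),
                         "C_dual": ("C_top",)},
        concept_groups={"C_top": ("disease",), "C_leaf": ("disease",),
                        "C_dual": ("drug", "procedure")},
        term_freq={"broad": 994, "narrow": 1, "dual": 5},
    )


def records_frame(rows):
    """rows: (user_id, ts, lat, lon, tokens) tuples -> canonical frame."""
    return pd.DataFrame(rows, columns=["user_id", "ts", "lat", "lon", "tokens"])
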