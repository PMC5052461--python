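"""Detect facility visits from log geometry and build the analysis cohort.

A visit is a contiguous run of one user's searches inside a facility's
200 m geofence dwelling >= 900 s.  The cohort filters drop probable
staff/residents, controls are matched on search-day counts, and every
member is partitioned into a 41-search-day window before their endpoint.
"""

import geoseek as gs

world = gs.generate_world(gs.WorldConfig(seed=7))
records, _ = gs.generate_users(
    world, gs.CohortConfig(n_patients=40, n_controls=50, seed=8))

policy = gs.GeofencePolicy()  # 200 m, 900 s, <=15/month, <=5 facilities, 42 days
visits = gs.detect_facility_visits(records, world.facilities, policy)
patients = gs.apply_cohort_filters(records, visits, world.facilities, policy)
controls = gs.sample_controls(records, patients, visits, policy, seed=9)
windows = gs.build_windows(records, patients, controls, policy, seed=10)

print(f"visit events: {len(visits)} (median dwell {visits['dwell_s'].median():.0f} s)")
print(f"patients after filters: {len(patients)}")
print(f"matched controls: {len(controls)} "
      f"({controls['exact_match'].mean():.0%} exact day-count matches)")
print(f"analysis windows: {len(windows)}, each with "
      f"{windows[0].records['day_bucket'].nunique()} search-day buckets")
# Day bucket 1 is the search day closest to the endpoint (the visit date
# for patients, a random date for controls); the endpoint day is excluded.
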