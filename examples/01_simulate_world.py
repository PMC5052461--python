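"""Generate a synthetic world and seeded user search streams.

Builds the static geography (facilities, landmark gazetteer), the toy
medical lexicon, and a small cohort of patient/control search logs, then
prints what was planted.
"""

import geoseek as gs

world = gs.generate_world(gs.WorldConfig(seed=7))
records, truth = gs.generate_users(
    world, gs.CohortConfig(n_patients=40, n_controls=50, seed=8))

print(f"facilities: {len(world.facilities)}, landmarks: {len(world.landmarks)}")
print(f"lexicon terms: {len(world.lexicon.terms)} "
      f"(groups: disease/drug/device/procedure)")
print(f"records: {len(records)} searches from {truth['user_id'].nunique()} users")

patients = truth[truth["label"] == "patient"]
print(f"patients: {len(patients)}, mean latent risk "
      f"{patients['latent_risk'].mean():.2f} "
      f"(controls {truth[truth.label == 'control']['latent_risk'].mean():.2f})")
# Patients escalate health searching in the final 15 days before their
# facility visit; controls emit the same stationary baseline throughout.
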