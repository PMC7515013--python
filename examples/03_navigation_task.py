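"""The grid-navigation learning task and its action-result indirection.

Builds the corridor fixture, shows the 24 action-to-result mappings, and
runs an oracle that knows the current mapping: it scores exactly
512 / 32 = 16 goals per episode, the task's performance ceiling.
"""

import numpy as np

from animatphi import (ACTION_MAPPINGS, OraclePolicy, evaluate_all_mappings,
                       make_fixture, run_episode, world_to_text)

world = make_fixture("corridor_world")
print("corridor world (G = goal, E = arrow pointing east):")
print(world_to_text(world))

print(f"{len(ACTION_MAPPINGS)} action->result mappings; the first three:")
for m in ACTION_MAPPINGS[:3]:
    print("  ", {chr(65 + a): r.name for a, r in enumerate(m)})

rng = np.random.default_rng(1)
mapping = ACTION_MAPPINGS[10]
res = run_episode(OraclePolicy(mapping), world, mapping, rng, lifetime=512,
                  face_arrow_on_spawn=True)
print(f"\noracle episode: {res.goals_reached} goals in 512 steps "
      f"(spawn distance 32 -> ceiling 512/32 = 16)")

total, _ = evaluate_all_mappings(
    lambda m: OraclePolicy(ACTION_MAPPINGS[m]), world, rng, lifetime=512,
    face_arrow_on_spawn=True)
print(f"oracle Gtotal over all 24 mappings: {total} (= 24 x 16)")
print("\nan evolved animat sees only the arrow under it, not the mapping: "
      "it must discover by trial and error which of A-D moves it forward.")
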