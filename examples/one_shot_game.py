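"""The one-shot deterrence game: payoffs, equilibria and the indifference
probability Q*.

A challenger can take a defender's resource (value v) or respect it; after
a take the defender yields or fights, a fight costing both parties c in
expectation.  This script prints the stage payoffs, the static equilibrium
report, and the fighting probability Q* = v/(c+v) at which a challenger is
exactly indifferent between taking and respecting.
"""

import json

from deterrence import PayoffParams, one_shot_equilibria, q_star, stage_payoffs

params = PayoffParams(v=1.0, c=1.5, a=0.1)

print("stage payoffs (challenger, defender):")
for play in [("respect", None), ("take", "yield"), ("take", "fight")]:
    print(f"  {play[0]:>7}/{play[1] or '-':<6} -> {stage_payoffs(*play, params)}")
print(f"  and a challenger who checked reputation first pays a={params.a} on top.")

print(f"\nQ* = v/(c+v) = {q_star(params):.3f}")
print("A defender who fights with at least this probability deters taking;")
print("below it, taking has positive expected value.")

print("\none-shot equilibrium report:")
print(json.dumps(one_shot_equilibria(params), indent=2))
print("Take-and-yield is the unique subgame-perfect outcome: the respect/"
      "fight equilibria rest on a retaliation threat that is empty once the"
      " resource is actually taken.")
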