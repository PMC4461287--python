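"""Build a small signed network, derive its Boolean rules, and relax
phenotype states to attractors.

A node is active iff at least one retained activator is active and no
retained inhibitor is (inhibitor-dominant rule); in-degree-0 nodes are
external inputs and hold their state.  All nodes update simultaneously.
"""

import boolprune as bp

# a tiny regulatory motif: S is an external signal, SNAIL represses CDH1,
# CDH1 and ZEB mutually... kept abstract: S -> A -| B, B -> B
net = bp.SignedDigraph.from_edges(
    [
        ("S", "A", bp.ACTIVATION),
        ("A", "B", bp.INHIBITION),
        ("B", "B", bp.ACTIVATION),
    ]
)
rules = bp.build_rules(net)
print("Update rules:")
print(rules.to_text())

for name, state in [
    ("signal on ", {"S": 1, "A": 0, "B": 1}),
    ("signal off", {"S": 0, "A": 0, "B": 1}),
]:
    traj = bp.run_to_attractor(rules, state)
    print(f"{name}: {state} -> {traj.outcome} {traj.attractor_state} "
          f"after {traj.steps_taken} step(s)")

# With the signal on, A switches on and shuts B down (the inhibitor
# dominates B's self-activation); with it off, B's self-activation
# maintains the B-high state.  Two stable phenotypes from one topology.
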