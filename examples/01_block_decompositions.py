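"""Decompose a unidirectional multistate graph into inference blocks.

The five-state progressive scheme (entry condition -> added conditions ->
death) has eight permitted transitions.  Blockwise inference factorises the
posterior either by competing-risk block (all exits from one state) or by
single transition.
"""

import msjoint as mj

graph = mj.five_state_progressive_graph(
    labels={0: "T2D", 1: "T2D+CVD", 2: "T2D+MH", 3: "T2D+CVD+MH", 4: "death"})
mj.validate_graph(graph)

print(f"states: {graph.states}, absorbing: {graph.absorbing_states}")
print(f"{len(graph.transitions)} permitted transitions")

cr = mj.competing_risk_blocks(graph)
print(f"\n{len(cr)} competing-risk blocks (one per non-absorbing state):")
for b in cr:
    exits = ", ".join(graph.label(k) for k in b.terminal_states)
    print(f"  from {graph.label(b.initial_state)}: competing exits -> {exits}")

st = mj.single_transition_blocks(graph)
print(f"\n{len(st)} single-transition blocks (one survival model each)")

ext = mj.five_state_extended_graph()
print(f"\nextended graph: {len(ext.transitions)} transitions, "
      f"{len(mj.competing_risk_blocks(ext))} CR blocks, "
      f"{len(mj.single_transition_blocks(ext))} ST blocks")
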