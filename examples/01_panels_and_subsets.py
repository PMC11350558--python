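"""Inspect the shipped panels and their gating trees.

Loads the three built-in 14-marker panels and prints, for each, the
marker registry and the tree of gates with the reported subset
variables.  The two peripheral-blood panels together resolve 42
reported immune subsets.
"""

from immunogate import count_reported_subsets, load_builtin


def show(name: str) -> None:
    panel, hierarchy = load_builtin(name)
    print(f"\n=== {name} panel: {len(panel.markers)} markers ===")
    print(", ".join(m.marker_name for m in panel.markers))

    def walk(node, depth=0):
        flag = " *" if node.reported else ""
        conds = ", ".join(f"{c.channel} {c.relation}" for c in node.conditions)
        print(f"  {'  ' * depth}{node.node_name}{flag}" + (f"  [{conds}]" if conds else ""))
        for ch in node.children:
            walk(ch, depth + 1)

    walk(hierarchy.root)
    print(f"reported subsets (*): {len(hierarchy.reported_nodes())}")


for name in ("myeloid", "lymphoid", "intracellular"):
    show(name)

m, l = load_builtin("myeloid")[1], load_builtin("lymphoid")[1]
print(f"\nperipheral panels jointly report {count_reported_subsets([m, l])} subsets")
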