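"""Simulate one blood sample, gate it, and recover absolute counts.

Generates a 50k-event myeloid-panel sample with known ground truth,
runs automatic hierarchical gating (asinh transform, mixture-based
thresholds), converts gated counts to cells/µL of whole blood, and
prints estimated vs true concentrations per reported subset.  With
well-separated expression levels the estimates land within a few
percent of truth.
"""

from immunogate import gate_sample, load_builtin
from immunogate.quantify import quantify_sample
from immunogate.synthetic import (
    default_study_config,
    draw_animal_effects,
    expected_node_concentrations,
    generate_sample,
)

cfg = default_study_config("myeloid", seed=11, events_per_sample=50_000)
events, truth = generate_sample(cfg, draw_animal_effects(cfg, 0), 0)
_, hierarchy = load_builtin("myeloid")

result = gate_sample(events, hierarchy, seed=0)
counts = quantify_sample(result, events).table.set_index("node")
true_conc = expected_node_concentrations(hierarchy, truth, cfg.populations)

print(f"sample {events.sample_id}: {events.n_events} events, "
      f"dilution factor {(events.blood_volume + events.diluent_volume) / events.blood_volume:.0f}")
print(f"{'subset':28s} {'events':>7s} {'cells/µL est':>12s} {'cells/µL true':>13s}")
for node in hierarchy.reported_nodes():
    est = counts.loc[node.node_name]
    print(f"{node.node_name:28s} {int(est['count']):7d} {est['cells_per_uL']:12.1f} "
          f"{true_conc[node.node_name]:13.1f}")
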