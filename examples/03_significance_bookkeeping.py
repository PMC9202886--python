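"""Replicate merging, replicated-interaction selection and curation.

Emulates the per-fragment p/q tables an upstream interaction caller
produces for two cell types (two replicates each), selects fragments
significant in both replicates of at least one cell type (q < 0.1),
merges replicate q values geometrically, curates locally most
significant fragments, and counts shared vs cell-type-specific calls.
"""

from deltacc import (
    GenomicInterval,
    InteractionSets,
    add_merged_q,
    classify_sets,
    curate_local_peaks,
    merge_q,
    replicated_significant,
)
from deltacc.simulate import default_scenario, simulate_significance

fragments, vp = default_scenario().build_fragments(seed=5)
shared = GenomicInterval("chrS", vp.midpoint + 20_000, vp.midpoint + 24_000)
neuron_only = GenomicInterval("chrS", vp.midpoint - 80_000, vp.midpoint - 76_000)

tables = {
    "esc": simulate_significance(fragments, [shared], seed=6),
    "neuron": simulate_significance(fragments, [shared, neuron_only], seed=7),
}

print("merge_q(0.04, 0.09) =", merge_q(0.04, 0.09))

sets = replicated_significant(tables, q_threshold=0.1)
for cell_type in sets.labels:
    print(f"{cell_type}: {len(sets[cell_type])} replicated-significant fragments")

counts = classify_sets(sets)
for labels, n in sorted(counts.items(), key=lambda kv: -len(kv[0])):
    print(f"  in exactly {{{', '.join(sorted(labels))}}}: {n}")

merged = add_merged_q(tables["neuron"])
curated = curate_local_peaks(merged, window=2, q_threshold=0.05)
print(f"curated {len(curated)} locally most-significant fragments:")
for f in curated:
    print("  ", f)
# The shared region replicates in both cell types, the second region in
# neurons only; curation thins each cluster of significant fragments to
# its local significance maxima (no two within the window of each other).
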