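"""Recover a planted anti-correlated miRNA-target network.

A synthetic bundle plants consistently changing microRNAs, mirrors some
into a second species, and wires their validated targets to move in the
opposite direction.  The pipeline gates each omics layer for significance
and keeps validated edges whose endpoints are anti-correlated; recovery is
scored against the generator's ground truth.
"""

from mirconcord import (
    SyntheticConfig,
    evaluate_recovery,
    find_consistent_connections,
    gate_consistent_genes,
    gate_consistent_mirnas,
    generate_bundle,
    summarize_network,
)

config = SyntheticConfig(n_mirnas=80, n_genes=300, frac_consistent_mirnas=0.2,
                         effect_size_log2=2.0, anti_correlation_fidelity=1.0,
                         seed=42)
bundle = generate_bundle(config)

significant_mirnas = gate_consistent_mirnas(bundle.human_mirna)   # both comparisons
gated_genes = gate_consistent_genes(bundle.gene_de)               # both gene studies
connections = find_consistent_connections(significant_mirnas, gated_genes,
                                          bundle.targets)

s = summarize_network(connections)
print(f"consistent connections: {s.n_connections}")
print(f"microRNAs involved:     {s.n_mirnas}")
print(f"target genes:           {s.n_targets} ({s.n_targets_up} up, "
      f"{s.n_targets_down} down in the first condition)")

metrics = evaluate_recovery(bundle.truth, connections=connections)["connections"]
print(f"recovery vs planted truth: precision={metrics.precision:.2f} "
      f"recall={metrics.recall:.2f}")

# At full anti-correlation fidelity every planted edge is recovered and
# nothing else: connection counts distinguish edges from unique genes
# because one miRNA opposes many targets (and vice versa).
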