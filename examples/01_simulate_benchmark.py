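"""Generate a synthetic benchmark with a planted modular regulatory network.

Four regulatory programs of 5 TFs each drive disjoint blocks of 50
target genes; the first program responds to the stress condition (its
TFs shift by delta under stress) and its TFs form the labeled positive
class. Prints the planted dimensions and the label split.
"""

from grain import simulate

gt = simulate.simulate_grn(seed=7)
expr = simulate.simulate_expression(gt, n_control=75, n_stress=75, seed=8)
labels = simulate.export_labels(gt)

print(f"TFs:             {len(gt.tf_ids)}")
print(f"target genes:    {len(gt.target_ids)}")
print(f"true edges:      {len(gt.true_edges)} "
      f"(background rate {gt.background_edge_rate})")
print(f"expression:      {expr.n_genes} genes x {expr.n_samples} samples")
print(f"positive TFs:    {sorted(gt.positive_tfs)}")
print(f"label split:     {len(labels.positives)} positive / "
      f"{len(labels.negatives)} negative")
# The positive TFs are the stress program's regulators; everything
# downstream tries to recover exactly this set from expression alone.
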