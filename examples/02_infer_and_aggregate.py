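"""Infer regulatory edges with three engines and build their consensus.

Each engine ranks candidate TF -> gene edges from expression alone; the
average-rank consensus reinforces edges that rank well everywhere. The
printed AUPR measures how far true planted edges rise above false
candidates (higher is better; the prevalence line is the score of a
random ranking).
"""

from grain import consensus, inference, simulate
from grain.evaluation import aupr_against_truth

gt = simulate.simulate_grn(seed=7)
expr = simulate.simulate_expression(gt, n_control=75, n_stress=75, seed=8)
tfs = gt.regulator_set()
universe = {(t, g) for t in gt.tf_ids for g in gt.gene_ids if g != t}
truth = set(gt.true_edges)

lists = []
for method in ("clr", "aracne", "genie3"):
    edges = inference.infer(method, expr, tfs, top_k=len(universe),
                            n_trees=100, seed=1)
    lists.append(edges)
    aupr = aupr_against_truth(edges, truth, universe)
    print(f"{method:>8}: {len(edges):5d} ranked edges, AUPR = {aupr:.3f}")

cons = consensus.consensus_network(lists, len(universe))
print(f"consensus: {len(cons):5d} ranked edges, AUPR = "
      f"{aupr_against_truth(cons, truth, universe):.3f}")
print(f"prevalence (random-ranking AUPR): {len(truth) / len(universe):.3f}")
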