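"""Reference-network construction and network-quality metrics.

Inferred edge lists are compared to independent (tf, gene) pair sets —
ChIP targets, co-annotation pairs, motif hits, protein interactions —
by precision (fraction of predicted edges in the reference), recall
(fraction of reference edges predicted) and their harmonic mean F1. A
benchmark TF counts as "recovered" when at least one of its reference
targets is predicted.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ValidationError
from .types import GeneSetCollection, RankedEdgeList, RegulatorSet

Edge = tuple[str, str]


@dataclass
class ReferenceNetwork:
    """An independent set of (tf, gene) pairs used to gauge inferred
    network quality."""

    source: str
    pairs: frozenset[Edge]

    def __init__(self, source: str, pairs: Iterable[Edge]):
        self.source = source
        self.pairs = frozenset(pairs)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class MetricRecord:
    precision: float
    recall: float
    f1: float
    n_true_positive: int
    n_predicted: int
    n_reference: int
    flagged: bool = False


def metrics(predicted: Iterable[Edge], reference: Iterable[Edge]) -> MetricRecord:
    """Precision/recall/F1 of a predicted edge set against a reference.

    Precision is defined as 0 for an empty prediction; an empty
    reference is an error.
    """
    pred = set(predicted)
    ref = set(reference)
    if not ref:
        raise ValidationError("reference edge set is empty")
    tp = len(pred & ref)
    precision = tp / len(pred) if pred else 0.0
    recall = tp / len(ref)
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return MetricRecord(
        precision=precision, recall=recall, f1=f1,
        n_true_positive=tp, n_predicted=len(pred), n_reference=len(ref),
        flagged=not pred,
    )


def per_tf_benchmark(
    network: RankedEdgeList,
    chip: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Per-TF precision/recall/F1 against per-TF reference target sets.

    A TF is recovered when at least one reference target is predicted;
    TFs with no predicted targets get zeroed metrics and a flag.
    """
    targets = network.targets_of()
    rows = []
    for tf in sorted(chip):
        ref = set(chip[tf])
        if not ref:
            raise ValidationError(f"benchmark TF {tf!r} has an empty target set")
        pred = targets.get(tf, set())
        if pred:
            rec = metrics({(tf, g) for g in pred}, {(tf, g) for g in ref})
        else:
            rec = MetricRecord(0.0, 0.0, 0.0, 0, 0, len(ref), flagged=True)
        rows.append({
            "tf": tf, "precision": rec.precision, "recall": rec.recall,
            "f1": rec.f1, "n_true_positive": rec.n_true_positive,
            "n_predicted": rec.n_predicted, "n_reference": rec.n_reference,
            "recovered": rec.n_true_positive >= 1, "flagged": rec.flagged,
        })
    return pd.DataFrame(rows)


def build_coannotation_reference(
    collection: GeneSetCollection,
    tfs: RegulatorSet,
    max_set_size: int = 200,
) -> ReferenceNetwork:
    """(tf, gene) pairs for every TF / non-TF gene co-annotated in an
    annotation set of fewer than ``max_set_size`` genes."""
    if len(collection) == 0:
        raise ValidationError("empty gene set collection")
    pairs: set[Edge] = set()
    for sid in collection:
        members = collection.genes(sid)
        if len(members) >= max_set_size:
            continue
        set_tfs = sorted(members & tfs.tf_ids)
        others = sorted(members - tfs.tf_ids)
        for tf in set_tfs:
            for gene in others:
                pairs.add((tf, gene))
    return ReferenceNetwork(source="coannotation", pairs=pairs)


def build_motif_reference(
    hits: Iterable[tuple[str, str, float]],
    n_genes_total: int,
    constitutive_fraction: float = 0.5,
    p_max: float = 1e-10,
) -> ReferenceNetwork:
    """(tf, gene) pairs from motif-scan hits.

    A TF whose motif hits more than ``constitutive_fraction`` of all
    genes is treated as a constitutive element and dropped entirely;
    surviving hits are kept at p-value strictly below ``p_max``.
    """
    hits = list(hits)
    genes_of: dict[str, set[str]] = {}
    for tf, gene, _ in hits:
        genes_of.setdefault(tf, set()).add(gene)
    n_distinct = len({g for _, g, _ in hits})
    if n_genes_total < n_distinct:
        raise ValidationError(
            f"n_genes_total={n_genes_total} smaller than the {n_distinct} "
            "distinct genes in the hits"
        )
    constitutive = {
        tf for tf, genes in genes_of.items()
        if len(genes) / n_genes_total > constitutive_fraction
    }
    pairs = {
        (tf, gene) for tf, gene, p in hits
        if tf not in constitutive and p < p_max
    }
    return ReferenceNetwork(source="motif", pairs=pairs)


def edge_overlap_counts(lists: Sequence[RankedEdgeList]) -> pd.DataFrame:
    """Exact-subset intersection sizes over all nonempty method subsets.

    The count for subset S is the number of edges present in exactly
    the methods of S; the counts sum to the size of the union.
    """
    if len(lists) < 2:
        raise ValidationError("overlap counts need at least 2 edge lists")
    tags = [el.method for el in lists]
    if len(set(tags)) != len(tags):
        raise ValidationError(f"duplicate method tag(s): {tags}")
    membership: dict[Edge, set[str]] = {}
    for el in lists:
        for edge in el.edge_set():
            membership.setdefault(edge, set()).add(el.method)
    counts: dict[frozenset, int] = {}
    for r in range(1, len(tags) + 1):
        for combo in combinations(tags, r):
            counts[frozenset(combo)] = 0
    for members in membership.values():
        counts[frozenset(members)] += 1
    rows = []
    for subset, count in counts.items():
        row = {tag: (tag in subset) for tag in tags}
        row["n_methods"] = len(subset)
        row["count"] = count
        rows.append(row)
    df = pd.DataFrame(rows).sort_values(
        ["n_methods"] + tags, ascending=[True] + [False] * len(tags),
        kind="mergesort",
    ).reset_index(drop=True)
    return df


def aupr_against_truth(
    edges: RankedEdgeList,
    true_edges: Iterable[Edge],
    universe: Iterable[Edge] | None = None,
) -> float:
    """AUPR of a ranked edge list against a ground-truth edge set.

    Edges are scored by their list position; candidate edges absent
    from the list (including true edges the list missed) are appended
    in one tied block at infinitely bad rank. ``universe`` is the full
    candidate edge space; by default it is the union of the list and
    the truth set, which overstates tail precision for heavily
    truncated lists — pass the real candidate space when comparing
    methods that truncate differently.
    """
    from .scoring import auc_pr
    import numpy as np

    truth = set(true_edges)
    if not truth:
        raise ValidationError("empty ground-truth edge set")
    df = edges.edges
    listed = list(zip(df["regulator"], df["target"]))
    listed_set = set(listed)
    if universe is None:
        missing = sorted(truth - listed_set)
    else:
        missing = sorted(set(universe) - listed_set)
    labels = [e in truth for e in listed] + [e in truth for e in missing]
    y = np.array(labels)
    s = np.concatenate([
        -df["rank"].to_numpy(dtype=float),
        np.full(len(missing), -np.inf),
    ])
    return auc_pr(y, s)
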