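"""Co-regulation projection, Markov clustering, TF x module features and
module enrichment.

The consensus network is a bipartite TF -> target graph. It is
projected onto target genes by linking pairs of genes whose predicted
regulator sets overlap strongly (Jaccard index at or above a quantile
of the nonzero Jaccard values). The resulting weighted co-regulation
graph is clustered with the Markov clustering algorithm (MCL),
implemented here in full: self-loops, column-stochastic normalization,
alternating expansion (matrix squaring) and inflation (entrywise power
and renormalization) with pruning of vanishing entries, until the
matrix reaches its attractor state. TFs are then tied to modules by the
Jaccard index of their predicted target sets with module gene sets,
giving the TF x module feature matrix used by the classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import ConvergenceError, ValidationError
from .types import GeneSetCollection, RankedEdgeList

logger = logging.getLogger(__name__)


def jaccard(a: Iterable, b: Iterable) -> float:
    """|A n B| / |A u B|; 0 when both sets are empty."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def regulator_sets(consensus: RankedEdgeList) -> dict[str, set[str]]:
    """Map every target gene of the consensus to its set of predicted
    regulators."""
    if len(consensus) == 0:
        raise ValidationError("consensus edge list is empty")
    out: dict[str, set[str]] = {}
    for reg, tgt in zip(consensus.edges["regulator"], consensus.edges["target"]):
        out.setdefault(tgt, set()).add(reg)
    return out


@dataclass
class CoRegulationGraph:
    """Undirected weighted graph over target genes; weights are Jaccard
    indices of regulator sets, thresholded at a quantile."""

    graph: nx.Graph
    unassigned: tuple[str, ...]
    threshold: float


def coregulation_graph(reg_sets: Mapping[str, set], quantile: float = 0.95
                       ) -> CoRegulationGraph:
    """Link gene pairs whose regulator-set Jaccard index reaches the
    ``quantile`` of all nonzero Jaccard values (ties included).

    Genes with no surviving edge are reported as unassigned.
    """
    if not (0 < quantile < 1):
        raise ValidationError("quantile must be in (0, 1)")
    genes = sorted(g for g, regs in reg_sets.items() if regs)
    # candidate pairs share at least one regulator
    by_reg: dict[str, list[str]] = {}
    for g in genes:
        for r in reg_sets[g]:
            by_reg.setdefault(r, []).append(g)
    pairs: set[tuple[str, str]] = set()
    for members in by_reg.values():
        pairs.update(combinations(members, 2))
    jis = {
        pair: jaccard(reg_sets[pair[0]], reg_sets[pair[1]]) for pair in pairs
    }
    nonzero = np.array([v for v in jis.values() if v > 0])
    if nonzero.size == 0:
        raise ValidationError(
            "degenerate consensus: no gene pair shares any regulator"
        )
    threshold = float(np.quantile(nonzero, quantile))
    graph = nx.Graph()
    for (u, v), w in sorted(jis.items()):
        if w > 0 and w >= threshold:
            graph.add_edge(u, v, weight=w)
    unassigned = tuple(sorted(set(genes) - set(graph.nodes)))
    return CoRegulationGraph(graph=graph, unassigned=unassigned, threshold=threshold)


@dataclass
class ModulePartition:
    """Disjoint gene modules; ids M0001... ordered by decreasing size."""

    modules: dict[str, tuple[str, ...]]
    unassigned: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for mid, genes in self.modules.items():
            overlap = seen & set(genes)
            if overlap:
                raise ValidationError(
                    f"modules are not disjoint: {sorted(overlap)[:3]}"
                )
            seen |= set(genes)

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    def genes(self) -> set[str]:
        return {g for genes in self.modules.values() for g in genes}

    def labels(self) -> dict[str, str]:
        return {g: mid for mid, genes in self.modules.items() for g in genes}

    def to_gene_sets(self) -> GeneSetCollection:
        return GeneSetCollection(
            sets={mid: (f"module of {len(genes)} genes", genes)
                  for mid, genes in self.modules.items()}
        )

    @classmethod
    def from_clusters(cls, clusters: Sequence[set[str]],
                      unassigned: Iterable[str] = ()) -> "ModulePartition":
        singles = [c for c in clusters if len(c) < 2]
        keep = [c for c in clusters if len(c) >= 2]
        keep.sort(key=lambda c: (-len(c), min(c)))
        modules = {
            f"M{i + 1:04d}": tuple(sorted(c)) for i, c in enumerate(keep)
        }
        extra = sorted({g for c in singles for g in c} | set(unassigned))
        return cls(modules=modules, unassigned=tuple(extra))


# -- Markov clustering --------------------------------------------------------

_MCL_PRUNE = 1e-5
_MCL_TOL = 1e-8
_MCL_MAX_ITER = 200


def _mcl_iterate(matrix: np.ndarray, inflation: float) -> np.ndarray:
    m = matrix.copy()
    for _ in range(_MCL_MAX_ITER):
        prev = m
        m = m @ m                      # expansion
        m = np.power(m, inflation)     # inflation
        m[m < _MCL_PRUNE] = 0.0
        colsum = m.sum(axis=0)
        colsum[colsum == 0] = 1.0
        m = m / colsum
        if np.max(np.abs(m - prev)) < _MCL_TOL:
            return m
    residual = float(np.max(np.abs(m - prev)))
    raise ConvergenceError(
        f"MCL did not converge in {_MCL_MAX_ITER} iterations "
        f"(residual {residual:.3g})", residual=residual,
    )


def mcl_cluster(coreg: CoRegulationGraph | nx.Graph,
                inflation: float = 2.0) -> ModulePartition:
    """Markov clustering of the co-regulation graph.

    Self-loops are set to each node's maximum incident weight, the
    adjacency is column-normalized, and expansion/inflation iterated to
    convergence. Clusters are read from attractor rows; a gene claimed
    by two attractor systems goes to the one holding more of its
    probability mass (ties: the system containing the lexicographically
    smallest gene). Singleton clusters are reported as unassigned.
    """
    if inflation <= 1:
        raise ValidationError("inflation must be > 1")
    pre_unassigned: tuple[str, ...] = ()
    if isinstance(coreg, CoRegulationGraph):
        pre_unassigned = coreg.unassigned
        graph = coreg.graph
    else:
        graph = coreg
    nodes = sorted(graph.nodes)
    if not nodes:
        raise ValidationError("empty co-regulation graph")
    index = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        adj[index[u], index[v]] = w
        adj[index[v], index[u]] = w
    loop = adj.max(axis=0)
    loop[loop == 0] = 1.0
    np.fill_diagonal(adj, loop)
    m = adj / adj.sum(axis=0)
    m = _mcl_iterate(m, inflation)

    attractors = [i for i in range(n) if m[i, i] > _MCL_PRUNE]
    # group attractor rows that share support into attractor systems
    sys_graph = nx.Graph()
    sys_graph.add_nodes_from(attractors)
    support = {i: set(np.nonzero(m[i])[0]) for i in attractors}
    for a, b in combinations(attractors, 2):
        if support[a] & support[b]:
            sys_graph.add_edge(a, b)
    systems = [sorted(c) for c in nx.connected_components(sys_graph)]
    systems.sort(key=lambda rows: nodes[rows[0]])

    clusters: list[set[str]] = [set() for _ in systems]
    for j in range(n):
        masses = np.array([m[rows, j].sum() for rows in systems])
        if masses.max() <= 0:  # orphaned column: attach to own attractor row
            continue
        best = np.flatnonzero(masses == masses.max())
        clusters[best[0]].add(nodes[j])
    return ModulePartition.from_clusters(clusters, unassigned=pre_unassigned)


# -- TF x module feature matrix ----------------------------------------------

def build_grain_matrix(consensus: RankedEdgeList,
                       partition: ModulePartition) -> pd.DataFrame:
    """TF x module matrix of Jaccard indices between each TF's predicted
    target set and each module's gene set. Rows cover every TF with at
    least one consensus target."""
    targets = consensus.targets_of()
    tf_list = sorted(tf for tf, tgts in targets.items() if tgts)
    dropped = sorted(set(targets) - set(tf_list))
    if dropped:
        logger.info("TF(s) with zero targets dropped: %s", dropped[:5])
    module_ids = list(partition.modules)
    data = np.zeros((len(tf_list), len(module_ids)))
    module_sets = {mid: set(genes) for mid, genes in partition.modules.items()}
    for i, tf in enumerate(tf_list):
        tset = targets[tf]
        for j, mid in enumerate(module_ids):
            data[i, j] = jaccard(tset, module_sets[mid])
    return pd.DataFrame(data, index=tf_list, columns=module_ids)


# -- enrichment ---------------------------------------------------------------

@dataclass
class EnrichmentResult:
    """One (module, gene set) hypergeometric test."""

    module_id: str
    set_id: str
    overlap: int
    module_size: int
    set_size: int
    universe_size: int
    p_value: float
    q_value: float = float("nan")
    significant: bool = False


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up BH adjusted q-values (monotone in p-value rank)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


def enrich_modules(
    partition: ModulePartition,
    collection: GeneSetCollection,
    universe: Iterable[str],
    min_size: int = 3,
    max_size: int = 500,
    q_threshold: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric upper-tail enrichment of annotation sets in each
    module, BH-corrected jointly across all (module, set) tests.

    Sets annotating fewer than ``min_size`` or more than ``max_size``
    genes are dropped before testing.
    """
    universe = set(universe)
    outside = partition.genes() - universe
    if outside:
        raise ValidationError(
            f"module gene(s) outside the universe: {sorted(outside)[:5]}"
        )
    surviving = {
        sid: collection.genes(sid) & universe
        for sid in collection
        if min_size <= len(collection.genes(sid)) <= max_size
    }
    results: list[EnrichmentResult] = []
    n_universe = len(universe)
    for mid, genes in partition.modules.items():
        module = set(genes)
        for sid, members in surviving.items():
            k = len(module & members)
            p = float(hypergeom.sf(k - 1, n_universe, len(members), len(module)))
            results.append(
                EnrichmentResult(
                    module_id=mid, set_id=sid, overlap=k,
                    module_size=len(module), set_size=len(members),
                    universe_size=n_universe, p_value=min(p, 1.0),
                )
            )
    if results:
        qs = benjamini_hochberg([r.p_value for r in results])
        for r, q in zip(results, qs):
            r.q_value = float(q)
            r.significant = q < q_threshold
    return results


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "module_id": r.module_id, "set_id": r.set_id,
                "overlap": r.overlap, "module_size": r.module_size,
                "set_size": r.set_size, "universe_size": r.universe_size,
                "p_value": r.p_value, "q_value": r.q_value,
                "significant": r.significant,
            }
            for r in results
        ]
    )


# -- ontology propagation -----------------------------------------------------

def propagate_annotations(
    collection: GeneSetCollection,
    ontology_edges: Iterable[tuple[str, str]],
) -> GeneSetCollection:
    """True-path propagation: each term's gene set becomes the union of
    its own genes and all its descendants' genes (a gene annotated to a
    child term is implicitly annotated to every ancestor).

    ``ontology_edges`` are (child, parent) pairs and must be acyclic.
    """
    dag = nx.DiGraph()
    dag.add_edges_from(ontology_edges)  # child -> parent
    try:
        cycle = nx.find_cycle(dag)
        raise ValidationError(f"ontology contains a cycle through {cycle[0][0]!r}")
    except nx.NetworkXNoCycle:
        pass
    genes: dict[str, set[str]] = {
        sid: set(g) for sid, (_, g) in collection.sets.items()
    }
    desc: dict[str, str] = {
        sid: d for sid, (d, _) in collection.sets.items()
    }
    for term in dag.nodes:
        genes.setdefault(term, set())
    # accumulate child genes into parents in topological (child-first) order
    for child in nx.topological_sort(dag):
        for parent in dag.successors(child):
            genes[parent] |= genes[child]
    out = {
        sid: (desc.get(sid, ""), tuple(sorted(g)))
        for sid, g in genes.items() if g
    }
    ordered = {sid: out[sid] for sid in collection.sets if sid in out}
    for sid in sorted(out):
        ordered.setdefault(sid, out[sid])
    return GeneSetCollection(sets=ordered)
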