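"""Network proximity test for stress-specific differentially expressed TLM genes.

Given an undirected, unweighted interaction network over genes, a set of
telomere-length-maintenance (TLM) genes, and per-stress DE sets, the test asks
whether the TLM genes that respond specifically to one stress lie closer to
each other on the network than the remaining TLM genes. Proximity is the
multiset of pairwise shortest-path lengths within a gene set; the comparison
is a one-sided Wilcoxon rank-sum test (specific DE-TLM distances smaller).
A specificity control repeats the comparison against specific DE genes that
are *not* TLM, to show closeness is not a generic property of DE genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

__all__ = [
    "GeneNetwork",
    "ProximityResult",
    "load_network",
    "pairwise_distances",
    "wilcoxon_rank_sum",
    "proximity_test",
    "specificity_control",
]


@dataclass
class GeneNetwork:
    """Simple undirected graph over gene IDs with TLM and per-stress DE flags."""

    graph: nx.Graph
    tlm: set = field(default_factory=set)
    de_by_stress: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.graph.remove_edges_from(nx.selfloop_edges(self.graph))
        nodes = set(self.graph.nodes)
        self.tlm = set(self.tlm) & nodes
        self.de_by_stress = {
            s: set(g) & nodes for s, g in self.de_by_stress.items()
        }

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    def specific_de(self, stress: str) -> set:
        """Genes DE under `stress` and under no other stress in the annotation."""
        others = [s for s in self.de_by_stress if s != stress]
        out = set(self.de_by_stress.get(stress, set()))
        for t in others:
            out -= self.de_by_stress[t]
        return out


@dataclass(frozen=True)
class ProximityResult:
    """One proximity comparison: two distance multisets and the rank-sum test."""

    dist_a: tuple
    dist_b: tuple
    statistic: float
    p: float
    n_excluded_pairs: int
    comparison: str


def load_network(edge_list, tlm_list=None, de_sets=None) -> GeneNetwork:
    """Build a GeneNetwork from an edge-list file plus optional annotations.

    `edge_list`: path to a two-column whitespace/tab-separated file; lines
    starting with '#' are comments. Duplicate edges collapse; self-loops drop.
    `tlm_list`: path to a one-ID-per-line file. `de_sets`: mapping
    stress -> iterable of gene IDs, or a StressDESets (its `specific` map is
    NOT used here; `de` flags are attached). IDs absent from the graph are
    reported via a warning and dropped.
    """
    g = nx.Graph()
    n_dup = 0
    with open(edge_list) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2 or not all(parts):
                raise ValueError(f"{edge_list}: malformed edge at line {lineno}: {line!r}")
            u, v = parts
            if u == v:
                continue
            if g.has_edge(u, v):
                n_dup += 1
            g.add_edge(u, v)
    if n_dup:
        warnings.warn(f"{n_dup} duplicate edge line(s) collapsed", stacklevel=2)

    tlm: set = set()
    if tlm_list is not None:
        with open(tlm_list) as fh:
            tlm = {line.strip() for line in fh if line.strip() and not line.startswith("#")}
        missing = tlm - set(g.nodes)
        if missing:
            warnings.warn(
                f"{len(missing)} TLM gene(s) absent from the network; excluded",
                stacklevel=2,
            )

    de_by_stress: dict = {}
    if de_sets is not None:
        de_map = getattr(de_sets, "de", de_sets)
        for stress, genes in de_map.items():
            genes = set(genes)
            missing = genes - set(g.nodes)
            if missing:
                warnings.warn(
                    f"{len(missing)} DE gene(s) for {stress!r} absent from the "
                    "network; excluded",
                    stacklevel=2,
                )
            de_by_stress[stress] = genes
    return GeneNetwork(graph=g, tlm=tlm, de_by_stress=de_by_stress)


def pairwise_distances(net: GeneNetwork | nx.Graph, gene_set) -> tuple[list, int]:
    """Shortest-path lengths (edge counts) for every unordered pair in a set.

    Returns (distances, n_excluded) where n_excluded counts pairs with no
    connecting path; such pairs are excluded, not imputed.
    """
    g = net.graph if isinstance(net, GeneNetwork) else net
    genes = sorted(gene_set)
    if len(genes) < 2:
        raise ValueError(f"gene set must contain >= 2 genes, got {len(genes)}")
    missing = [x for x in genes if x not in g]
    if missing:
        raise ValueError(f"gene set members absent from network: {missing}")
    dists: list[int] = []
    excluded = 0
    for i, u in enumerate(genes):
        lengths = nx.single_source_shortest_path_length(g, u)
        for v in genes[i + 1 :]:
            if v in lengths:
                dists.append(lengths[v])
            else:
                excluded += 1
    return dists, excluded


def wilcoxon_rank_sum(a, b, alternative: str = "two-sided") -> tuple[float, float]:
    """Wilcoxon rank-sum test on two value multisets.

    Reports the rank-sum statistic W of sample `a` (average ranks for ties).
    The p-value is exact (full enumeration of assignments) when
    |a| + |b| <= 16 and there are no ties; otherwise the normal approximation
    with tie-corrected variance and continuity correction is used.
    `alternative='less'` tests that values in `a` tend to be smaller.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("less", "greater", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")

    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w = float(ranks[: a.size].sum())

    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across both samples; p = 1", stacklevel=2)
        return w, 1.0

    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size + b.size <= 16 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return w, float(res.pvalue)


def proximity_test(
    net: GeneNetwork,
    stress: str,
    b_definition: str = "other_tlm",
    alternative: str = "less",
) -> ProximityResult:
    """Test whether stress-specific DE-TLM genes are mutually closer than other TLM genes.

    dist_a: pairwise distances within TLM ∩ specific-DE(stress).
    dist_b: with `b_definition='other_tlm'` (default), pairwise distances
    within the remaining TLM genes; with 'all_other_tlm_pairs', all TLM pairs
    not entirely inside the specific set. One-sided by default (a closer).
    """
    set_a = net.specific_de(stress) & net.tlm
    if len(set_a) < 2:
        raise ValueError(
            f"stress-specific DE-TLM set for {stress!r} has {len(set_a)} gene(s); "
            "need >= 2"
        )
    dist_a, excl_a = pairwise_distances(net, set_a)

    if b_definition == "other_tlm":
        set_b = net.tlm - set_a
        if len(set_b) < 2:
            raise ValueError(
                f"other-TLM set for {stress!r} has {len(set_b)} gene(s); need >= 2"
            )
        dist_b, excl_b = pairwise_distances(net, set_b)
    elif b_definition == "all_other_tlm_pairs":
        all_d, excl_all = pairwise_distances(net, net.tlm)
        # remove the within-set-a pairs from the all-TLM pair multiset
        dist_b = list(all_d)
        for d in dist_a:
            dist_b.remove(d)
        excl_b = excl_all - excl_a
    else:
        raise ValueError(f"unknown b_definition {b_definition!r}")

    if not dist_a or not dist_b:
        raise ValueError("a distance multiset is empty (disconnected set?)")
    stat, p = wilcoxon_rank_sum(dist_a, dist_b, alternative=alternative)
    return ProximityResult(
        dist_a=tuple(dist_a),
        dist_b=tuple(dist_b),
        statistic=stat,
        p=p,
        n_excluded_pairs=excl_a + excl_b,
        comparison=f"{stress}: specific DE-TLM vs {b_definition}",
    )


def specificity_control(
    full_net: GeneNetwork, stress: str, alternative: str = "less"
) -> ProximityResult:
    """Control: are specific DE-TLM genes closer than specific DE non-TLM genes?

    Run on the full interaction network. A small p here alongside a small
    proximity_test p shows mutual closeness is a property of the DE *TLM*
    genes, not of DE genes in general.
    """
    specific = full_net.specific_de(stress)
    set_a = specific & full_net.tlm
    set_b = specific - full_net.tlm
    if len(set_a) < 2:
        raise ValueError(
            f"specific DE-TLM set for {stress!r} has {len(set_a)} gene(s); need >= 2"
        )
    if len(set_b) < 2:
        raise ValueError(
            f"specific DE non-TLM set for {stress!r} has {len(set_b)} gene(s); "
            "need >= 2 — control undefined"
        )
    dist_a, excl_a = pairwise_distances(full_net, set_a)
    dist_b, excl_b = pairwise_distances(full_net, set_b)
    if not dist_a or not dist_b:
        raise ValueError("a distance multiset is empty (disconnected set?)")
    stat, p = wilcoxon_rank_sum(dist_a, dist_b, alternative=alternative)
    return ProximityResult(
        dist_a=tuple(dist_a),
        dist_b=tuple(dist_b),
        statistic=stat,
        p=p,
        n_excluded_pairs=excl_a + excl_b,
        comparison=f"{stress}: specific DE-TLM vs specific DE non-TLM",
    )
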