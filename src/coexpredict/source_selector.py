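"""Coverage analysis and source-gene panel selection.

A target gene is "covered" by a source gene when it lies within ``max_jumps``
edges of it.  Panel selection is greedy maximum-marginal-coverage set cover
over a candidate list drawn from strongly correlated edges, optionally
supplemented with high-degree genes from the uncovered remainder.  Every
operation is deterministic: all tie-breaks are lexicographic.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from coexpredict.network_builder import CoexpressionNetwork, NetworkError

DEFAULT_MAX_JUMPS = 4


@dataclass
class CoverageReport:
    """Reachability of a source panel within a jump limit."""

    sources: list[str]
    max_jumps: int
    reachable: set[str]
    per_target_min_jumps: dict[str, int]
    per_target_source_count: dict[str, int]

    @property
    def coverage(self) -> int:
        return len(self.reachable)


def source_balls(
    net: CoexpressionNetwork, sources: list[str], max_jumps: int
) -> dict[str, set[str]]:
    """Per-source set of genes within ``max_jumps`` edges (source excluded)."""
    if max_jumps < 1:
        raise ValueError(f"max_jumps must be >= 1, got {max_jumps}")
    balls: dict[str, set[str]] = {}
    for source in sources:
        if source not in net:
            raise NetworkError(f"source gene {source!r} not in network")
        dist = nx.single_source_shortest_path_length(
            net.graph, source, cutoff=max_jumps
        )
        balls[source] = {g for g in dist if g != source}
    return balls


def reachable_set(
    net: CoexpressionNetwork,
    sources: list[str],
    max_jumps: int = DEFAULT_MAX_JUMPS,
) -> CoverageReport:
    """Breadth-first coverage report for a source panel.

    Targets are genes within ``max_jumps`` of at least one source; the source
    genes themselves are excluded from the target set.  ``per_target_source_count``
    counts, for every gene in the union of per-source balls (including genes
    that are themselves sources), how many sources reach it.
    """
    sources = list(sources)
    balls = source_balls(net, sources, max_jumps)
    count: Counter[str] = Counter()
    for ball in balls.values():
        count.update(ball)
    source_set = set(sources)
    reachable = set(count) - source_set
    min_jumps: dict[str, int] = {}
    for source in sources:
        dist = nx.single_source_shortest_path_length(
            net.graph, source, cutoff=max_jumps
        )
        for gene, d in dist.items():
            if gene in reachable and (gene not in min_jumps or d < min_jumps[gene]):
                min_jumps[gene] = d
    return CoverageReport(
        sources=sources,
        max_jumps=max_jumps,
        reachable=reachable,
        per_target_min_jumps=min_jumps,
        per_target_source_count={g: count[g] for g in reachable},
    )


@dataclass
class PathLengthHistogram:
    counts: dict[int, int]
    disconnected: int = 0

    def total_pairs(self) -> int:
        return sum(self.counts.values()) + self.disconnected

    def modal_length(self) -> int | None:
        if not self.counts:
            return None
        return min(self.counts, key=lambda k: (-self.counts[k], k))


def path_length_histogram(
    net: CoexpressionNetwork,
    node_pairs: list[tuple[str, str]] | None = None,
    sample: int | None = None,
    seed: int | None = None,
) -> PathLengthHistogram:
    """Distribution of shortest-path lengths over node pairs.

    All unordered pairs by default; ``node_pairs`` restricts to the given
    pairs, ``sample`` draws that many pairs at random (seeded).  Pairs without
    a connecting path are tallied under ``disconnected``.
    """
    nodes = net.nodes
    if node_pairs is None:
        node_pairs = list(itertools.combinations(nodes, 2))
        if sample is not None and sample < len(node_pairs):
            rng = np.random.default_rng(seed)
            idx = rng.choice(len(node_pairs), size=sample, replace=False)
            node_pairs = [node_pairs[i] for i in sorted(idx)]
    counts: Counter[int] = Counter()
    disconnected = 0
    for u, v in node_pairs:
        try:
            counts[nx.shortest_path_length(net.graph, u, v)] += 1
        except nx.NetworkXNoPath:
            disconnected += 1
    return PathLengthHistogram(counts=dict(sorted(counts.items())), disconnected=disconnected)


def candidate_sources(
    net: CoexpressionNetwork, criterion: str, cutoff: float
) -> list[str]:
    """Genes with at least one incident edge passing the strength criterion.

    ``criterion`` is ``"abs_r"`` (``|r| > cutoff``) or ``"r_squared"``
    (``r**2 > cutoff``).  Returns a sorted gene-id list.
    """
    if not (0.0 < cutoff < 1.0):
        raise ValueError(f"cutoff must be in (0, 1), got {cutoff}")
    if criterion == "abs_r":
        passes = lambda r: abs(r) > cutoff  # noqa: E731
    elif criterion == "r_squared":
        passes = lambda r: r * r > cutoff  # noqa: E731
    else:
        raise ValueError(f"unknown criterion {criterion!r}; use abs_r or r_squared")
    hits: set[str] = set()
    for model in net.edges():
        if passes(model.r):
            hits.add(model.gene_a)
            hits.add(model.gene_b)
    return sorted(hits)


def greedy_minimal_sources(
    net: CoexpressionNetwork,
    candidates: list[str],
    max_jumps: int = DEFAULT_MAX_JUMPS,
) -> list[str]:
    """Redundancy removal by greedy maximum-marginal-coverage set cover.

    Repeatedly picks the candidate whose jump-ball adds the most not-yet
    covered genes (ties broken by lexicographic id) and stops once no
    candidate adds coverage.  A selected source counts as covered itself (its
    expression is known), so the returned panel's coverage — union of
    jump-balls plus the panel — equals that of the full candidate list.
    """
    candidates = list(candidates)
    if not candidates:
        return []
    balls = source_balls(net, candidates, max_jumps)
    covered: set[str] = set()
    selected: list[str] = []
    remaining = sorted(set(candidates))
    while remaining:
        best_gene = None
        best_gain = 0
        for gene in remaining:
            gain = len((balls[gene] | {gene}) - covered)
            if gain > best_gain:
                best_gain, best_gene = gain, gene
        if best_gene is None:
            break
        selected.append(best_gene)
        covered |= balls[best_gene] | {best_gene}
        remaining.remove(best_gene)
    return selected


def supplement_by_degree(
    net: CoexpressionNetwork,
    selected: list[str],
    k: int,
    max_jumps: int = DEFAULT_MAX_JUMPS,
) -> list[str]:
    """Add the ``k`` highest-degree genes from the uncovered remainder.

    "Uncovered" means not in ``selected`` and not within ``max_jumps`` of any
    selected gene.  Ties on degree break lexicographically.  Returns
    ``selected`` followed by the additions.
    """
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    selected = list(selected)
    if k == 0:
        return selected
    covered: set[str] = set(selected)
    if selected:
        for ball in source_balls(net, selected, max_jumps).values():
            covered |= ball
    uncovered = [g for g in net.nodes if g not in covered]
    uncovered.sort(key=lambda g: (-net.degree(g), g))
    return selected + uncovered[:k]
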