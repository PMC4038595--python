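"""Chained-regression transcriptome prediction.

A target gene's expression is estimated by composing the directed affine
model of every edge along a simple path from a source gene, once per
enumerated path; the predictor reports the arithmetic mean and standard
deviation over the per-path estimates.

Single-pass mode assigns each target exactly one source — the nearest by
jump count, ties broken by position in the source list — and never
re-estimates a target.  Multi-pass mode pools path-level estimates across
every source that reaches the target.
"""

from __future__ import annotations

import math
from collections.abc import Mapping
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from coexpredict.data_model import SourceValues, as_value_dict
from coexpredict.network_builder import CoexpressionNetwork, NetworkError

DEFAULT_MAX_JUMPS = 4
DEFAULT_MAX_PATHS = 10_000


@dataclass(frozen=True)
class PathEnumerationPolicy:
    """How source-to-target paths are enumerated.

    Enumeration is exhaustive over simple paths of at most ``max_len`` edges
    in deterministic lexicographic neighbor order, truncated after
    ``max_paths`` paths.  With ``sample=True`` the cap is instead filled by a
    seeded uniform draw from the full enumeration.  ``min_paths_note`` is
    informational only: it records the lower end of the path-count range the
    method was evaluated on.
    """

    max_len: int = DEFAULT_MAX_JUMPS
    max_paths: int = DEFAULT_MAX_PATHS
    sample: bool = False
    seed: int | None = None
    min_paths_note: int = 30

    def __post_init__(self) -> None:
        if self.max_len < 1:
            raise ValueError(f"max_len must be >= 1, got {self.max_len}")
        if self.max_paths < 1:
            raise ValueError(f"max_paths must be >= 1, got {self.max_paths}")


@dataclass
class PredictionResult:
    """Per-target prediction summary.

    ``sd`` is the sample standard deviation over path-level estimates and is
    ``None`` when only one path exists (such targets are excluded from
    SD-based evaluation).  ``adjacent`` flags 1-jump targets.
    """

    target: str
    mean: float
    sd: float | None
    n_paths: int
    jumps: int
    sources_used: list[str]
    adjacent: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.n_paths < 1:
            raise ValueError("n_paths must be >= 1")
        if self.sd is not None and self.sd < 0:
            raise ValueError("sd must be >= 0")


def enumerate_paths(
    net: CoexpressionNetwork,
    source: str,
    target: str,
    policy: PathEnumerationPolicy = PathEnumerationPolicy(),
) -> list[list[str]]:
    """All simple paths from source to target with at most ``max_len`` edges.

    Paths are produced by depth-first search visiting neighbors in sorted
    order, so the output order (and hence any truncation at ``max_paths``) is
    deterministic.  Returns an empty list when no path exists.
    """
    if source == target:
        raise NetworkError("source and target must differ")
    for gene in (source, target):
        if gene not in net:
            raise NetworkError(f"gene {gene!r} not in network")
    paths: list[list[str]] = []
    limit = None if policy.sample else policy.max_paths
    _dfs_paths(net.graph, source, target, policy.max_len, [source], {source}, paths, limit)
    if policy.sample and len(paths) > policy.max_paths:
        rng = np.random.default_rng(policy.seed)
        idx = rng.choice(len(paths), size=policy.max_paths, replace=False)
        paths = [paths[i] for i in sorted(idx)]
    return paths


def _dfs_paths(
    graph: nx.Graph,
    node: str,
    target: str,
    budget: int,
    prefix: list[str],
    visited: set[str],
    out: list[list[str]],
    limit: int | None,
) -> bool:
    """Depth-first enumeration; returns False once ``limit`` paths collected."""
    if budget == 0:
        return True
    for nxt in sorted(graph.neighbors(node)):
        if nxt == target:
            out.append(prefix + [nxt])
            if limit is not None and len(out) >= limit:
                return False
            continue
        if nxt in visited:
            continue
        visited.add(nxt)
        prefix.append(nxt)
        ok = _dfs_paths(graph, nxt, target, budget - 1, prefix, visited, out, limit)
        prefix.pop()
        visited.remove(nxt)
        if not ok:
            return False
    return True


def chain_predict(
    path: list[str], source_value: float, net: CoexpressionNetwork
) -> float:
    """Compose the directed affine edge models along ``path``.

    The result is affine in ``source_value`` with slope equal to the product
    of the per-edge slopes.  Raises if any consecutive pair is not an edge.
    """
    if len(path) < 2:
        raise NetworkError("path must contain at least one edge")
    value = float(source_value)
    for u, v in zip(path, path[1:]):
        b1, b0 = net.coefficients(u, v)
        value = b1 * value + b0
    return value


def _summarize(values: list[float]) -> tuple[float, float | None]:
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size >= 2 else None
    return mean, sd


def _prepare_sources(
    net: CoexpressionNetwork,
    source_values: "SourceValues | Mapping[str, float]",
    strict: bool,
) -> dict[str, float]:
    values = as_value_dict(source_values)
    missing = [g for g in values if g not in net]
    if missing:
        if strict:
            raise NetworkError(
                f"source gene(s) not in network: {', '.join(missing)}"
            )
        values = {g: v for g, v in values.items() if g not in missing}
    if not values:
        raise NetworkError("no source gene present in the network")
    return values


def _distances(
    net: CoexpressionNetwork, sources: list[str], max_len: int
) -> dict[str, dict[str, int]]:
    return {
        s: nx.single_source_shortest_path_length(net.graph, s, cutoff=max_len)
        for s in sources
    }


def predict_single_pass(
    net: CoexpressionNetwork,
    source_values: "SourceValues | Mapping[str, float]",
    policy: PathEnumerationPolicy = PathEnumerationPolicy(),
    strict: bool = True,
) -> dict[str, PredictionResult]:
    """Predict each reachable target from exactly one source gene.

    The assigned source is the one at minimal jump distance; among equally
    near sources the one listed first wins.  A predicted target is never
    re-estimated.  Returns a target-id-sorted dict.
    """
    values = _prepare_sources(net, source_values, strict)
    order = list(values)
    dist = _distances(net, order, policy.max_len)
    source_set = set(order)
    targets: set[str] = set()
    for s in order:
        targets.update(g for g in dist[s] if g not in source_set)
    results: dict[str, PredictionResult] = {}
    for target in sorted(targets):
        best: tuple[int, int] | None = None
        for pos, s in enumerate(order):
            d = dist[s].get(target)
            if d is None:
                continue
            key = (d, pos)
            if best is None or key < best:
                best = key
        assert best is not None
        jumps, pos = best
        source = order[pos]
        paths = enumerate_paths(net, source, target, policy)
        preds = [chain_predict(p, values[source], net) for p in paths]
        mean, sd = _summarize(preds)
        results[target] = PredictionResult(
            target=target,
            mean=mean,
            sd=sd,
            n_paths=len(preds),
            jumps=jumps,
            sources_used=[source],
            adjacent=jumps == 1,
        )
    return results


def predict_multi_pass(
    net: CoexpressionNetwork,
    source_values: "SourceValues | Mapping[str, float]",
    policy: PathEnumerationPolicy = PathEnumerationPolicy(),
    strict: bool = True,
) -> dict[str, PredictionResult]:
    """Predict each target by pooling path estimates over all reaching sources.

    Path-level predictions from every source within ``max_len`` jumps are
    concatenated; mean/SD are taken over the pooled set and ``n_paths`` is
    the pooled count.  The covered target set is identical to single-pass.
    """
    values = _prepare_sources(net, source_values, strict)
    order = list(values)
    dist = _distances(net, order, policy.max_len)
    source_set = set(order)
    targets: set[str] = set()
    for s in order:
        targets.update(g for g in dist[s] if g not in source_set)
    results: dict[str, PredictionResult] = {}
    for target in sorted(targets):
        pooled: list[float] = []
        used: list[str] = []
        jumps = None
        for s in order:
            d = dist[s].get(target)
            if d is None:
                continue
            paths = enumerate_paths(net, s, target, policy)
            if not paths:
                continue
            pooled.extend(chain_predict(p, values[s], net) for p in paths)
            used.append(s)
            jumps = d if jumps is None else min(jumps, d)
        assert pooled and jumps is not None
        mean, sd = _summarize(pooled)
        results[target] = PredictionResult(
            target=target,
            mean=mean,
            sd=sd,
            n_paths=len(pooled),
            jumps=jumps,
            sources_used=used,
            adjacent=jumps == 1,
        )
    return results
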