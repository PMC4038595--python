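"""Co-expression network construction.

Every unordered pair of rows in the expression matrix is scored by Pearson
correlation; pairs whose absolute correlation exceeds the threshold become
undirected edges that carry the ordinary-least-squares affine model in both
directions, so prediction can traverse an edge either way.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
from scipy import special

from coexpredict._util import atomic_write
from coexpredict.data_model import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.75

_EDGE_FIELDS = ("r", "n", "b1_ab", "b0_ab", "b1_ba", "b0_ba")


class NetworkError(ValueError):
    """Invalid network construction or lookup."""


class DegenerateEdgeError(NetworkError):
    """A correlation/regression fit on a zero-variance vector."""


def pair_count(p: int) -> int:
    """Number of unordered pairs among ``p`` items, ``p*(p-1)/2``."""
    p = int(p)
    if p < 0:
        raise ValueError(f"item count must be non-negative, got {p}")
    return p * (p - 1) // 2


@dataclass(frozen=True)
class EdgeModel:
    """One network edge: correlation plus both directed affine fits.

    ``b1_ab``/``b0_ab`` predict ``gene_a`` from ``gene_b``; ``b1_ba``/``b0_ba``
    predict ``gene_b`` from ``gene_a``.  The least-squares identity
    ``b1_ab * b1_ba == r**2`` holds up to floating-point error.
    """

    gene_a: str
    gene_b: str
    r: float
    n: int
    b1_ab: float
    b0_ab: float
    b1_ba: float
    b0_ba: float

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise NetworkError(f"self-loop on {self.gene_a!r}")
        if abs(self.r) > 1 + 1e-12:
            raise NetworkError(f"|r| > 1 on edge {self.gene_a}-{self.gene_b}")
        if self.n < 3:
            raise NetworkError("edge sample count must be >= 3")

    def coefficients(self, source: str, target: str) -> tuple[float, float]:
        """Slope/intercept predicting ``target`` from ``source`` along this edge."""
        if source == self.gene_a and target == self.gene_b:
            return self.b1_ba, self.b0_ba
        if source == self.gene_b and target == self.gene_a:
            return self.b1_ab, self.b0_ab
        raise NetworkError(
            f"edge {self.gene_a}-{self.gene_b} does not connect "
            f"{source!r} -> {target!r}"
        )

    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.gene_a, self.gene_b)))  # type: ignore[return-value]


def fit_edge(
    x: np.ndarray,
    y: np.ndarray,
    gene_a: str = "x",
    gene_b: str = "y",
) -> EdgeModel:
    """Fit correlation and both OLS orientations for one gene pair.

    ``x`` plays the role of ``gene_a`` and ``y`` of ``gene_b``.  Raises
    :class:`DegenerateEdgeError` when either vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise NetworkError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise NetworkError(f"need >= 3 observations, got {n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise NetworkError("non-finite values in fit_edge input")
    mx, my = x.mean(), y.mean()
    dx, dy = x - mx, y - my
    var_x = float(dx @ dx)
    var_y = float(dy @ dy)
    if var_x == 0.0 or var_y == 0.0:
        raise DegenerateEdgeError(
            f"zero variance in pair ({gene_a!r}, {gene_b!r})"
        )
    cov = float(dx @ dy)
    r = cov / math.sqrt(var_x * var_y)
    r = max(-1.0, min(1.0, r))
    b1_ba = cov / var_x  # predict y (gene_b) from x (gene_a)
    b0_ba = my - b1_ba * mx
    b1_ab = cov / var_y
    b0_ab = mx - b1_ab * my
    return EdgeModel(gene_a, gene_b, r, n, b1_ab, b0_ab, b1_ba, b0_ba)


def corr_pvalue_bonferroni(r: float, n: int, m: int) -> float:
    """Bonferroni-corrected two-sided p-value for a Pearson correlation.

    Uses the exact identity ``p = I_{1-r^2}(df/2, 1/2)`` for the two-sided
    tail of ``t = r*sqrt(df/(1-r^2))`` with ``df = n-2`` degrees of freedom,
    which stays accurate far below double underflow of the naive survival
    function.  The raw p-value is multiplied by ``m`` tests and capped at 1.
    """
    n = int(n)
    m = int(m)
    if n < 3:
        raise ValueError(f"need n >= 3 samples, got {n}")
    if m < 1:
        raise ValueError(f"need m >= 1 tests, got {m}")
    if abs(r) > 1:
        raise ValueError(f"|r| must be <= 1, got {r}")
    if abs(r) == 1.0:
        return 0.0
    df = n - 2
    p = float(special.betainc(df / 2.0, 0.5, 1.0 - r * r))
    return min(1.0, p * m)


class CoexpressionNetwork:
    """Undirected co-expression graph whose edges carry :class:`EdgeModel`s.

    Nodes are the genes incident to at least one retained edge.  Genes that
    survived variance filtering but gained no edge are recorded in
    ``isolated_genes``; zero-variance genes dropped before correlation are in
    ``dropped_genes``.  Neither group is part of the graph.
    """

    def __init__(self, threshold: float = DEFAULT_THRESHOLD) -> None:
        if not (0.0 <= threshold < 1.0):
            raise NetworkError(f"threshold must be in [0, 1), got {threshold}")
        self.threshold = float(threshold)
        self.graph = nx.Graph()
        self.dropped_genes: list[str] = []
        self.isolated_genes: list[str] = []

    # -- construction -----------------------------------------------------
    def add_edge(self, model: EdgeModel) -> None:
        if abs(model.r) <= self.threshold:
            raise NetworkError(
                f"edge {model.gene_a}-{model.gene_b} has |r|={abs(model.r):.4f}"
                f" <= threshold {self.threshold}"
            )
        self.graph.add_edge(model.gene_a, model.gene_b, model=model)

    # -- queries ----------------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def __contains__(self, gene: object) -> bool:
        return gene in self.graph

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors(self, gene: str) -> list[str]:
        self._require(gene)
        return sorted(self.graph.neighbors(gene))

    def degree(self, gene: str) -> int:
        self._require(gene)
        return int(self.graph.degree[gene])

    def edge_model(self, u: str, v: str) -> EdgeModel:
        try:
            return self.graph.edges[u, v]["model"]
        except KeyError:
            raise NetworkError(f"no edge between {u!r} and {v!r}") from None

    def coefficients(self, source: str, target: str) -> tuple[float, float]:
        """Directed (slope, intercept) predicting ``target`` from ``source``."""
        return self.edge_model(source, target).coefficients(source, target)

    def edges(self) -> list[EdgeModel]:
        models = [data["model"] for _, _, data in self.graph.edges(data=True)]
        return sorted(models, key=EdgeModel.key)

    def _require(self, gene: str) -> None:
        if gene not in self.graph:
            raise NetworkError(f"gene {gene!r} not in network")

    # -- serialization ----------------------------------------------------
    def to_graphml(self, path: str | Path) -> None:
        g = nx.Graph(threshold=self.threshold)
        g.graph["dropped_genes"] = ",".join(self.dropped_genes)
        g.graph["isolated_genes"] = ",".join(self.isolated_genes)
        for model in self.edges():
            g.add_edge(
                model.gene_a,
                model.gene_b,
                gene_a=model.gene_a,
                gene_b=model.gene_b,
                r=model.r,
                n=int(model.n),
                b1_ab=model.b1_ab,
                b0_ab=model.b0_ab,
                b1_ba=model.b1_ba,
                b0_ba=model.b0_ba,
            )
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        nx.write_graphml(g, path)

    @classmethod
    def from_graphml(cls, path: str | Path) -> "CoexpressionNetwork":
        g = nx.read_graphml(path)
        net = cls(threshold=float(g.graph.get("threshold", DEFAULT_THRESHOLD)))
        for key in ("dropped_genes", "isolated_genes"):
            raw = g.graph.get(key, "")
            setattr(net, key, [s for s in str(raw).split(",") if s])
        for _, _, data in g.edges(data=True):
            model = EdgeModel(
                gene_a=str(data["gene_a"]),
                gene_b=str(data["gene_b"]),
                r=float(data["r"]),
                n=int(data["n"]),
                b1_ab=float(data["b1_ab"]),
                b0_ab=float(data["b0_ab"]),
                b1_ba=float(data["b1_ba"]),
                b0_ba=float(data["b0_ba"]),
            )
            net.add_edge(model)
        return net

    def to_jsonl(self, path: str | Path) -> None:
        with atomic_write(path) as handle:
            meta = {
                "threshold": self.threshold,
                "dropped_genes": self.dropped_genes,
                "isolated_genes": self.isolated_genes,
            }
            handle.write(json.dumps({"meta": meta}) + "\n")
            for model in self.edges():
                record = {"gene_a": model.gene_a, "gene_b": model.gene_b}
                record.update({f: getattr(model, f) for f in _EDGE_FIELDS})
                handle.write(json.dumps(record) + "\n")

    @classmethod
    def from_jsonl(cls, path: str | Path) -> "CoexpressionNetwork":
        with open(path, encoding="utf-8") as handle:
            first = json.loads(handle.readline())
            meta = first.get("meta", {})
            net = cls(threshold=float(meta.get("threshold", DEFAULT_THRESHOLD)))
            net.dropped_genes = list(meta.get("dropped_genes", []))
            net.isolated_genes = list(meta.get("isolated_genes", []))
            for line in handle:
                line = line.strip()
                if not line:
                    continue
                record = json.loads(line)
                net.add_edge(EdgeModel(**record))
        return net


def build_network(
    matrix: ExpressionMatrix,
    threshold: float = DEFAULT_THRESHOLD,
    block_size: int | None = None,
    pairwise_complete: bool = False,
    min_shared: int = 10,
) -> CoexpressionNetwork:
    """Threshold all pairwise Pearson correlations into a network.

    Exactly the pairs with ``|r| > threshold`` become edges, each fitted with
    both regression orientations.  Zero-variance rows are dropped with a
    warning; rows left without any retained edge are flagged as isolated.

    Correlations are computed blockwise (``block_size`` rows at a time); the
    result is independent of the block size because each pair's statistics are
    full dot products over the sample axis either way.  Matrices containing
    NaN require ``pairwise_complete=True`` and use, for each pair, the samples
    observed in both rows (at least ``min_shared``).
    """
    if matrix.n_samples < 3:
        raise NetworkError(
            f"need >= 3 samples to fit correlations, got {matrix.n_samples}"
        )
    if np.isnan(matrix.values).any():
        if not pairwise_complete:
            raise NetworkError(
                "matrix contains NaN; pass pairwise_complete=True"
            )
        return _build_pairwise_complete(matrix, threshold, min_shared)

    net = CoexpressionNetwork(threshold=threshold)
    values = matrix.values
    n = matrix.n_samples
    means = values.mean(axis=1)
    centered = values - means[:, None]
    sumsq = np.einsum("ij,ij->i", centered, centered)
    keep = sumsq > 0.0
    net.dropped_genes = [rid for rid, k in zip(matrix.row_ids, keep) if not k]
    if net.dropped_genes:
        logger.warning(
            "dropping %d zero-variance gene(s): %s",
            len(net.dropped_genes),
            ", ".join(net.dropped_genes[:10]),
        )
    ids = [rid for rid, k in zip(matrix.row_ids, keep) if k]
    centered = centered[keep]
    sumsq = sumsq[keep]
    means = means[keep]
    norms = np.sqrt(sumsq)
    z = centered / norms[:, None]

    p = len(ids)
    if block_size is None:
        block_size = max(1, min(p, 2048))
    edges: list[EdgeModel] = []
    for i0 in range(0, p, block_size):
        i1 = min(i0 + block_size, p)
        for j0 in range(i0, p, block_size):
            j1 = min(j0 + block_size, p)
            corr = z[i0:i1] @ z[j0:j1].T
            # screen with a small slack, then recompute each candidate pair's
            # r as a direct dot product: BLAS results can differ in the last
            # ulp between block shapes, and edges must not depend on blocking
            hits_i, hits_j = np.nonzero(np.abs(corr) > threshold - 1e-9)
            for bi, bj in zip(hits_i, hits_j):
                gi, gj = i0 + int(bi), j0 + int(bj)
                if gj <= gi:
                    continue
                r = float(np.clip(np.dot(z[gi], z[gj]), -1.0, 1.0))
                if abs(r) <= threshold:
                    continue
                edges.append(_edge_from_moments(
                    ids[gi], ids[gj], r, n,
                    means[gi], means[gj], norms[gi], norms[gj],
                ))
    return _assemble(net, edges, ids)


def _edge_from_moments(
    id_a: str,
    id_b: str,
    r: float,
    n: int,
    mean_a: float,
    mean_b: float,
    norm_a: float,
    norm_b: float,
) -> EdgeModel:
    # OLS slope predicting b from a is cov/var_a = r * norm_b / norm_a.
    if id_b < id_a:
        id_a, id_b = id_b, id_a
        mean_a, mean_b = mean_b, mean_a
        norm_a, norm_b = norm_b, norm_a
    b1_ba = r * norm_b / norm_a
    b0_ba = mean_b - b1_ba * mean_a
    b1_ab = r * norm_a / norm_b
    b0_ab = mean_a - b1_ab * mean_b
    return EdgeModel(id_a, id_b, r, n, b1_ab, b0_ab, b1_ba, b0_ba)


def _build_pairwise_complete(
    matrix: ExpressionMatrix, threshold: float, min_shared: int
) -> CoexpressionNetwork:
    net = CoexpressionNetwork(threshold=threshold)
    values = matrix.values
    mask = np.isfinite(values)
    ids = list(matrix.row_ids)
    edges: list[EdgeModel] = []
    dropped: set[str] = set()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            shared = mask[i] & mask[j]
            k = int(shared.sum())
            if k < max(min_shared, 3):
                continue
            x, y = values[i, shared], values[j, shared]
            if x.std() == 0.0 or y.std() == 0.0:
                if x.std() == 0.0:
                    dropped.add(ids[i])
                if y.std() == 0.0:
                    dropped.add(ids[j])
                continue
            model = fit_edge(x, y, ids[i], ids[j])
            if abs(model.r) > threshold:
                edges.append(model)
    net.dropped_genes = sorted(dropped)
    return _assemble(net, edges, [g for g in ids if g not in dropped])


def _assemble(
    net: CoexpressionNetwork, edges: list[EdgeModel], kept_ids: list[str]
) -> CoexpressionNetwork:
    incident: set[str] = set()
    for model in sorted(edges, key=EdgeModel.key):
        net.add_edge(model)
        incident.add(model.gene_a)
        incident.add(model.gene_b)
    net.isolated_genes = sorted(set(kept_ids) - incident)
    return net
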