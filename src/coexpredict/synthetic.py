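"""Seeded generators of expression compendia with known co-expression truth.

Modules are driven by independent latent factors: gene ``g`` in a module is
``a_g * latent + c_g + noise`` so every within-module pair is affinely
related with a known expected correlation, while cross-module pairs are
(asymptotically) uncorrelated.  Chain layouts arrange genes in layers with
true edges only between consecutive layers, which gives full control over
path topology for multi-jump prediction tests.

All randomness flows through one ``numpy`` generator created from the seed;
no global RNG state is touched.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from coexpredict.data_model import ExpressionMatrix, ProbeGeneMap
from coexpredict.network_builder import CoexpressionNetwork, EdgeModel


@dataclass
class SyntheticTruth:
    """Ground truth for a simulated compendium.

    ``true_edges`` maps a sorted gene-id pair to ``(b1, b0, expected_r)``
    where ``b1``/``b0`` predict the second id of the pair from the first.
    """

    true_edges: dict[tuple[str, str], tuple[float, float, float]]
    module_assignment: dict[str, int]
    noise_sd: dict[str, float]
    seed: int
    chain_layout: list[list[str]] | None = None
    gene_params: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "module_assignment": self.module_assignment,
            "noise_sd": self.noise_sd,
            "chain_layout": self.chain_layout,
            "gene_params": {g: list(p) for g, p in self.gene_params.items()},
            "true_edges": [
                {"gene_a": a, "gene_b": b, "b1": v[0], "b0": v[1], "r": v[2]}
                for (a, b), v in sorted(self.true_edges.items())
            ],
        }
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(payload, indent=1))


def _gene_values(
    rng: np.random.Generator,
    latent: np.ndarray,
    slope_range: tuple[float, float],
    baseline_range: tuple[float, float],
    noise_sd: float,
) -> tuple[np.ndarray, float, float]:
    a = float(rng.uniform(*slope_range))
    c = float(rng.uniform(*baseline_range))
    eps = rng.normal(0.0, noise_sd, size=latent.size) if noise_sd > 0 else 0.0
    return a * latent + c + eps, a, c


def _pair_truth(
    a1: float, c1: float, s1: float, a2: float, c2: float, s2: float
) -> tuple[float, float, float]:
    # latent has unit variance; exact affine relation g2 = (a2/a1) g1 + ...
    b1 = a2 / a1
    b0 = c2 - c1 * b1
    r = (a1 * a2) / math.sqrt((a1 * a1 + s1 * s1) * (a2 * a2 + s2 * s2))
    return b1, b0, r


def simulate_transcriptomes(
    module_sizes: list[int],
    n_samples: int,
    target_r: float | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    slope_range: tuple[float, float] = (0.75, 1.25),
    baseline_range: tuple[float, float] = (6.0, 12.0),
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate a modular compendium of affinely related genes.

    Each module is driven by one standard-normal latent factor.  With
    ``target_r`` set, per-gene residual noise is scaled so every
    within-module pair has expected correlation exactly ``target_r``;
    otherwise ``noise_sd`` is used as an absolute residual SD.  Gene ids sort
    as ``M<module>G<index>``.
    """
    if n_samples < 3:
        raise ValueError(f"need >= 3 samples, got {n_samples}")
    if any(k < 1 for k in module_sizes):
        raise ValueError("module sizes must be >= 1")
    if target_r is not None and not (0.0 < target_r <= 1.0):
        raise ValueError(f"target_r must be in (0, 1], got {target_r}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    row_ids: list[str] = []
    rows: list[np.ndarray] = []
    truth = SyntheticTruth(
        true_edges={}, module_assignment={}, noise_sd={}, seed=seed
    )
    for mod, size in enumerate(module_sizes):
        latent = rng.standard_normal(n_samples)
        params: list[tuple[str, float, float, float]] = []
        for g in range(size):
            gene = f"M{mod}G{g:03d}"
            a = float(rng.uniform(*slope_range))
            c = float(rng.uniform(*baseline_range))
            if target_r is not None:
                s = 0.0 if target_r == 1.0 else a * math.sqrt(1.0 / target_r - 1.0)
            else:
                s = noise_sd
            eps = rng.normal(0.0, s, size=n_samples) if s > 0 else np.zeros(n_samples)
            row_ids.append(gene)
            rows.append(a * latent + c + eps)
            truth.module_assignment[gene] = mod
            truth.noise_sd[gene] = s
            truth.gene_params[gene] = (a, c)
            params.append((gene, a, c, s))
        for i in range(size):
            for j in range(i + 1, size):
                g1, a1, c1, s1 = params[i]
                g2, a2, c2, s2 = params[j]
                truth.true_edges[(g1, g2)] = _pair_truth(a1, c1, s1, a2, c2, s2)
    matrix = ExpressionMatrix(row_ids, [f"S{i:04d}" for i in range(n_samples)], np.vstack(rows))
    return matrix, truth


def simulate_chain_network(
    layers: list[int],
    n_samples: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    skip_edges: list[tuple[tuple[int, int], tuple[int, int]]] | None = None,
    slope_range: tuple[float, float] = (0.75, 1.25),
    baseline_range: tuple[float, float] = (6.0, 12.0),
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate a layered chain of affinely related genes.

    All genes are affine in one latent factor, but the *true edge set*
    connects only consecutive layers (fully bipartite), plus any explicit
    ``skip_edges`` given as ``((layer_i, index_i), (layer_j, index_j))``.
    With ``noise_sd=0`` every true edge is an exact affine relation, so
    chained prediction recovers values exactly.  Gene ids sort as
    ``L<layer>N<index>``.
    """
    if len(layers) < 2:
        raise ValueError("need >= 2 layers")
    if any(k < 1 for k in layers):
        raise ValueError("layer sizes must be >= 1")
    if n_samples < 3:
        raise ValueError(f"need >= 3 samples, got {n_samples}")
    rng = np.random.default_rng(seed)
    latent = rng.standard_normal(n_samples)
    layout: list[list[str]] = []
    row_ids: list[str] = []
    rows: list[np.ndarray] = []
    truth = SyntheticTruth(
        true_edges={}, module_assignment={}, noise_sd={}, seed=seed, chain_layout=[]
    )
    params: dict[str, tuple[float, float, float]] = {}
    for li, size in enumerate(layers):
        layer_ids: list[str] = []
        for ni in range(size):
            gene = f"L{li}N{ni:02d}"
            values, a, c = _gene_values(rng, latent, slope_range, baseline_range, noise_sd)
            row_ids.append(gene)
            rows.append(values)
            layer_ids.append(gene)
            params[gene] = (a, c, noise_sd)
            truth.module_assignment[gene] = li
            truth.noise_sd[gene] = noise_sd
            truth.gene_params[gene] = (a, c)
        layout.append(layer_ids)
    truth.chain_layout = layout

    def add_edge(g1: str, g2: str) -> None:
        key = tuple(sorted((g1, g2)))
        a1, c1, s1 = params[key[0]]
        a2, c2, s2 = params[key[1]]
        truth.true_edges[key] = _pair_truth(a1, c1, s1, a2, c2, s2)  # type: ignore[index]

    for li in range(len(layers) - 1):
        for g1 in layout[li]:
            for g2 in layout[li + 1]:
                add_edge(g1, g2)
    for (li, ni), (lj, nj) in skip_edges or []:
        add_edge(layout[li][ni], layout[lj][nj])
    matrix = ExpressionMatrix(row_ids, [f"S{i:04d}" for i in range(n_samples)], np.vstack(rows))
    return matrix, truth


def simulate_random_walk_chain(
    length: int,
    n_samples: int,
    step_sd: float = 0.5,
    seed: int = 0,
    baseline: float = 8.0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate a chain where each gene adds fresh noise to its predecessor.

    ``g_0 = baseline + N(0, 1)`` per sample and ``g_k = g_{k-1} + N(0,
    step_sd)``, so the true edge relation between neighbors is the identity
    and prediction-error variance accumulates linearly with jump count —
    the generative structure behind accuracy-versus-jumps decay curves.
    Gene ids are ``W00 .. W<length-1>``.
    """
    if length < 2:
        raise ValueError("need a chain of >= 2 genes")
    if n_samples < 3:
        raise ValueError(f"need >= 3 samples, got {n_samples}")
    if step_sd < 0:
        raise ValueError("step_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = [baseline + rng.standard_normal(n_samples)]
    for _ in range(length - 1):
        rows.append(rows[-1] + rng.normal(0.0, step_sd, n_samples))
    row_ids = [f"W{i:02d}" for i in range(length)]
    truth = SyntheticTruth(
        true_edges={}, module_assignment={}, noise_sd={}, seed=seed,
        chain_layout=[[g] for g in row_ids],
    )
    for i, gene in enumerate(row_ids):
        truth.module_assignment[gene] = i
        truth.noise_sd[gene] = step_sd
        truth.gene_params[gene] = (1.0, 0.0)
        if i:
            var_lo = 1.0 + (i - 1) * step_sd**2
            var_hi = 1.0 + i * step_sd**2
            r = math.sqrt(var_lo / var_hi)
            truth.true_edges[(row_ids[i - 1], gene)] = (1.0, 0.0, r)
    matrix = ExpressionMatrix(
        row_ids, [f"S{i:04d}" for i in range(n_samples)], np.vstack(rows)
    )
    return matrix, truth


def simulate_duplicate_probes(
    matrix: ExpressionMatrix,
    genes: list[str],
    deviation_pct: float,
    seed: int = 0,
    array_noise_sd: float | None = None,
) -> tuple[ExpressionMatrix, ProbeGeneMap]:
    """Append a second probe per listed gene with multiplicative perturbation.

    The second probe's per-array values are the original values times
    ``(1 + sign*d) * lognormal`` with ``d = deviation_pct/100``, sign drawn
    per gene, and the lognormal jitter mean-unbiased; the intra-array
    variation estimator therefore recovers ``deviation_pct`` up to sampling
    noise.  The duplicated probe is named ``<gene>__dup`` and the returned
    map sends both probes to the gene (all other rows map to themselves).
    """
    if deviation_pct < 0:
        raise ValueError("deviation_pct must be >= 0")
    unknown = [g for g in genes if g not in matrix.row_ids]
    if unknown:
        raise ValueError(f"genes not in matrix: {', '.join(unknown)}")
    rng = np.random.default_rng(seed)
    d = deviation_pct / 100.0
    sigma = array_noise_sd if array_noise_sd is not None else d
    row_ids = list(matrix.row_ids)
    rows = [matrix.values[i].copy() for i in range(matrix.n_rows)]
    pairs = {rid: rid for rid in matrix.row_ids}
    for gene in genes:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        if sigma > 0:
            jitter = np.exp(rng.normal(0.0, sigma, matrix.n_samples) - sigma * sigma / 2.0)
        else:
            jitter = np.ones(matrix.n_samples)
        # measured ratio original/duplicate averages to 1 + sign*d
        ratio = (1.0 + sign * d) * jitter
        dup_id = f"{gene}__dup"
        row_ids.append(dup_id)
        rows.append(matrix.row(gene) / ratio)
        pairs[dup_id] = gene
    out = ExpressionMatrix(row_ids, list(matrix.sample_ids), np.vstack(rows))
    return out, ProbeGeneMap(pairs)


def network_from_truth(
    truth: SyntheticTruth,
    n_samples: int,
    threshold: float = 0.0,
) -> CoexpressionNetwork:
    """Build a network directly from a generator's true edge set.

    Edge coefficients are the generating affine relations (both orientations
    derived exactly), with ``r`` set to the expected correlation.  Useful for
    exact-recovery and topology-controlled tests where thresholding the
    empirical correlation matrix would add shortcut edges.
    """
    net = CoexpressionNetwork(threshold=threshold)
    for (g1, g2), (b1, b0, r) in sorted(truth.true_edges.items()):
        model = EdgeModel(
            gene_a=g1,
            gene_b=g2,
            r=r,
            n=n_samples,
            b1_ab=1.0 / b1,
            b0_ab=-b0 / b1,
            b1_ba=b1,
            b0_ba=b0,
        )
        net.add_edge(model)
    return net


def fit_network_on_truth(
    matrix: ExpressionMatrix,
    truth: SyntheticTruth,
    threshold: float = 0.0,
) -> CoexpressionNetwork:
    """Network with the true topology but edge models fitted to the data.

    Keeps the generator's edge set (so path structure is controlled) while
    every edge's correlation and regression coefficients come from ordinary
    least squares on the simulated matrix — the realistic setting where
    estimation noise propagates through chained prediction.
    """
    from coexpredict.network_builder import fit_edge

    net = CoexpressionNetwork(threshold=threshold)
    for g1, g2 in sorted(truth.true_edges):
        net.add_edge(fit_edge(matrix.row(g1), matrix.row(g2), g1, g2))
    return net
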