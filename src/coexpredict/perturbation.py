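"""In-silico gene perturbation and expression-buffer analysis.

A perturbation multiplies a gene's background expression by a ratio
(over-expression > 1, knockdown < 1, knockout = 0).  Effects are estimated by
two prediction passes over the genes reachable within the jump limit of the
perturbed genes — one pass from the unperturbed background values, one from
the ratio-scaled values — followed by per-gene classification: adjacent
(1-jump) genes by fold ratio, 2+-jump genes by a two-sample z-test with
Bonferroni correction.

Sweeping the ratio of one gene across a grid yields an affected-gene
response curve; fitting a quadratic and solving its roots gives the
"expression buffer", the ratio interval around 1 with no predicted effect.
"""

from __future__ import annotations

import math
from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from coexpredict.data_model import SourceValues, as_value_dict
from coexpredict.network_builder import CoexpressionNetwork, NetworkError
from coexpredict.predictor import (
    PathEnumerationPolicy,
    PredictionResult,
    predict_multi_pass,
    predict_single_pass,
)

DEFAULT_ALPHA = 0.05
DEFAULT_FOLD_THRESHOLD = 3.0


@dataclass
class PerturbationSpec:
    """Gene-id -> non-negative expression-ratio multiplier."""

    ratios: dict[str, float]

    def __post_init__(self) -> None:
        clean: dict[str, float] = {}
        for gene, ratio in self.ratios.items():
            ratio = float(ratio)
            if not math.isfinite(ratio) or ratio < 0:
                raise ValueError(
                    f"perturbation ratio for {gene!r} must be finite and >= 0,"
                    f" got {ratio}"
                )
            clean[str(gene)] = ratio
        self.ratios = clean

    @classmethod
    def load(cls, path) -> "PerturbationSpec":
        return cls(ratios=as_value_dict(SourceValues.load(path)))


@dataclass
class GeneCall:
    """Classification of one reachable gene after perturbation."""

    gene: str
    jumps: int
    baseline_mean: float
    perturbed_mean: float
    statistic_type: str  # "fold" (1-jump) or "z" (2+ jumps)
    statistic: float
    p_value: float | None  # Bonferroni-corrected; None for fold calls
    affected: bool


@dataclass
class PerturbationResult:
    """Two-pass prediction over the perturbed genes' reachable neighborhood."""

    spec: PerturbationSpec
    mode: str
    baseline: dict[str, PredictionResult]
    perturbed: dict[str, PredictionResult]
    calls: dict[str, GeneCall] = field(default_factory=dict)

    @property
    def affected(self) -> set[str]:
        return {g for g, call in self.calls.items() if call.affected}

    @property
    def reachable(self) -> set[str]:
        return set(self.baseline)


def apply_perturbations(
    background: "SourceValues | Mapping[str, float]", spec: PerturbationSpec
) -> SourceValues:
    """Scale the specified genes' background values by their ratios."""
    values = as_value_dict(background)
    for gene, ratio in spec.ratios.items():
        if gene not in values:
            raise KeyError(f"perturbed gene {gene!r} not in background values")
        values[gene] = values[gene] * ratio
    return SourceValues(values)


def predict_perturbation(
    net: CoexpressionNetwork,
    background: "SourceValues | Mapping[str, float]",
    spec: PerturbationSpec,
    policy: PathEnumerationPolicy = PathEnumerationPolicy(),
    mode: str = "single",
    alpha: float = DEFAULT_ALPHA,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
) -> PerturbationResult:
    """Two-pass prediction of a perturbation's transcriptome-wide effect.

    Only the perturbed genes act as sources; the reachable set is the union
    of their jump-limit neighborhoods.  Pass 1 uses the unperturbed
    background values of those genes, pass 2 the ratio-scaled values; the
    path sets are identical in both passes, so a null perturbation (all
    ratios 1) reproduces the baseline exactly.  The result comes
    pre-classified (see :func:`classify_affected`).
    """
    if mode not in ("single", "multi"):
        raise ValueError(f"mode must be 'single' or 'multi', got {mode!r}")
    if not spec.ratios:
        raise ValueError("perturbation spec is empty")
    background = as_value_dict(background)
    for gene in spec.ratios:
        if gene not in net:
            raise NetworkError(f"perturbed gene {gene!r} not in network")
        if gene not in background:
            raise KeyError(f"perturbed gene {gene!r} not in background values")
    base_sources = SourceValues({g: background[g] for g in spec.ratios})
    pert_sources = apply_perturbations(base_sources, spec)
    predict = predict_single_pass if mode == "single" else predict_multi_pass
    baseline = predict(net, base_sources, policy)
    perturbed = predict(net, pert_sources, policy)
    result = PerturbationResult(
        spec=spec, mode=mode, baseline=baseline, perturbed=perturbed
    )
    classify_affected(result, alpha=alpha, fold_threshold=fold_threshold)
    return result


def _fold_ratio(pre: float, post: float) -> float:
    if pre == post:
        return 1.0
    lo, hi = sorted((abs(pre), abs(post)))
    if lo == 0.0:
        return math.inf
    if pre * post < 0:  # sign flip on RMA scale: treat as unbounded change
        return math.inf
    return hi / lo


def classify_affected(
    result: PerturbationResult,
    alpha: float = DEFAULT_ALPHA,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
) -> set[str]:
    """Classify each reachable gene as affected or not.

    1-jump genes have a single path and no SD, so they are called by fold
    ratio: affected when ``max(pre, post)/min(pre, post) > fold_threshold``.
    Genes at 2+ jumps are called by a two-sample z-test on the two passes'
    (mean, sd, n_paths), Bonferroni-corrected over the number of z-tested
    genes; affected when the corrected p-value is below ``alpha``.

    Populates ``result.calls`` and returns the affected gene set.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if fold_threshold <= 1.0:
        raise ValueError(f"fold_threshold must be > 1, got {fold_threshold}")
    calls: dict[str, GeneCall] = {}
    z_genes = [
        g
        for g, base in result.baseline.items()
        if base.jumps >= 2
    ]
    m = max(1, len(z_genes))
    for gene, base in result.baseline.items():
        post = result.perturbed[gene]
        if base.jumps == 1:
            fold = _fold_ratio(base.mean, post.mean)
            calls[gene] = GeneCall(
                gene=gene,
                jumps=base.jumps,
                baseline_mean=base.mean,
                perturbed_mean=post.mean,
                statistic_type="fold",
                statistic=fold,
                p_value=None,
                affected=fold > fold_threshold,
            )
        else:
            z, p = _z_test(base, post)
            p_corr = min(1.0, p * m)
            calls[gene] = GeneCall(
                gene=gene,
                jumps=base.jumps,
                baseline_mean=base.mean,
                perturbed_mean=post.mean,
                statistic_type="z",
                statistic=z,
                p_value=p_corr,
                affected=p_corr < alpha,
            )
    result.calls = calls
    return result.affected


def _z_test(base: PredictionResult, post: PredictionResult) -> tuple[float, float]:
    """Welch-type two-sample z from (mean, sd, n_paths) of the two passes."""
    s1 = base.sd if base.sd is not None else 0.0
    s2 = post.sd if post.sd is not None else 0.0
    se = math.sqrt(s1 * s1 / base.n_paths + s2 * s2 / post.n_paths)
    diff = post.mean - base.mean
    if se == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        return math.copysign(math.inf, diff), 0.0
    z = diff / se
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return z, p


@dataclass
class BufferModel:
    """Quadratic fit of affected-gene response versus perturbation ratio."""

    gene: str
    ratios: list[float]
    counts: list[int]
    percentages: list[float]
    response: str  # "pct" or "count"
    coefficients: tuple[float, float, float] | None  # (a, b, c), a*x^2+b*x+c
    roots: tuple[float, float] | None
    buffer_interval: tuple[float, float] | None
    degenerate: bool = False
    diagnostic: str = ""


def fit_quadratic_response(
    ratios: list[float],
    responses: list[float],
    leading_tol: float = 1e-9,
) -> tuple[tuple[float, float, float] | None, tuple[float, float] | None, str]:
    """Least-squares quadratic fit plus closed-form roots.

    Returns ``(coefficients, roots, diagnostic)``.  Coefficients are ``None``
    when fewer than 3 distinct ratios are given; roots are ``None`` when the
    leading coefficient is (numerically) zero or the discriminant is
    negative.
    """
    xs = np.asarray(ratios, dtype=float)
    ys = np.asarray(responses, dtype=float)
    if len(set(xs.tolist())) < 3:
        return None, None, "need >= 3 distinct ratios for a quadratic fit"
    a, b, c = (float(v) for v in np.polyfit(xs, ys, 2))
    scale = max(abs(a), abs(b), abs(c), 1.0)
    if abs(a) <= leading_tol * scale:
        return (a, b, c), None, "degenerate fit: leading coefficient ~ 0"
    disc = b * b - 4.0 * a * c
    if disc < 0.0:
        return (a, b, c), None, "no real roots (discriminant < 0)"
    sq = math.sqrt(disc)
    r1 = (-b - sq) / (2.0 * a)
    r2 = (-b + sq) / (2.0 * a)
    lo, hi = sorted((r1, r2))
    return (a, b, c), (lo, hi), ""


def buffer_sweep(
    net: CoexpressionNetwork,
    background: "SourceValues | Mapping[str, float]",
    gene: str,
    grid: list[float],
    policy: PathEnumerationPolicy = PathEnumerationPolicy(),
    alpha: float = DEFAULT_ALPHA,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    mode: str = "single",
    response: str = "pct",
) -> BufferModel:
    """Sweep one gene's perturbation ratio and fit the response quadratic.

    For every ratio in ``grid`` the perturbation is predicted and classified;
    the response (percentage of the reachable set affected by default, raw
    counts with ``response="count"``) is fitted with an ordinary-least-squares
    quadratic whose real roots, when they bracket ratio 1, delimit the
    expression buffer (intersected with the grid range).
    """
    if response not in ("pct", "count"):
        raise ValueError(f"response must be 'pct' or 'count', got {response!r}")
    grid = [float(x) for x in grid]
    if len(set(grid)) < 3:
        raise ValueError("grid must contain >= 3 distinct ratios")
    counts: list[int] = []
    percentages: list[float] = []
    for ratio in grid:
        result = predict_perturbation(
            net,
            background,
            PerturbationSpec({gene: ratio}),
            policy=policy,
            mode=mode,
            alpha=alpha,
            fold_threshold=fold_threshold,
        )
        n_reach = len(result.reachable)
        n_aff = len(result.affected)
        counts.append(n_aff)
        percentages.append(100.0 * n_aff / n_reach if n_reach else 0.0)
    ys = percentages if response == "pct" else [float(c) for c in counts]
    coeffs, roots, diagnostic = fit_quadratic_response(grid, ys)
    buffer_interval = None
    if roots is not None:
        lo, hi = roots
        if lo < 1.0 < hi:
            buffer_interval = (max(lo, min(grid)), min(hi, max(grid)))
    return BufferModel(
        gene=gene,
        ratios=grid,
        counts=counts,
        percentages=percentages,
        response=response,
        coefficients=coeffs,
        roots=roots,
        buffer_interval=buffer_interval,
        degenerate=roots is None,
        diagnostic=diagnostic,
    )
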