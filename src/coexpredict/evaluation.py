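"""Evaluation metrics: percent-difference accuracy and intra-array variation.

Accuracy follows a within-threshold rule: a target counts as predicted
within X% when the actual value lies within +/- X% of the *predicted* value.
Intra-array (measurement) variation is estimated from genes measured by two
probes as the mean absolute deviation of their average value ratio from 1.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np
from scipy import stats

from coexpredict.data_model import ExpressionMatrix

logger = logging.getLogger(__name__)


class EvaluationError(ValueError):
    pass


@dataclass
class AccuracyReport:
    per_gene_pct_diff: dict[str, float]
    within_threshold: dict[float, float]  # threshold % -> fraction in [0, 1]
    correlation: float | None  # None when either vector is constant
    n_genes: int
    by_jumps: dict[int, "AccuracyReport"] | None = None


def _accuracy(
    genes: list[str],
    predicted: Mapping[str, float],
    actual: Mapping[str, float],
    thresholds: list[float],
) -> AccuracyReport:
    pct_diff: dict[str, float] = {}
    within = {float(t): 0 for t in thresholds}
    for g in genes:
        p, a = predicted[g], actual[g]
        if p == 0:
            pct_diff[g] = math.inf
        else:
            pct_diff[g] = abs(a - p) / abs(p) * 100.0
        for t in within:
            if abs(a - p) <= (t / 100.0) * abs(p):
                within[t] += 1
    n = len(genes)
    pred_vec = np.array([predicted[g] for g in genes], dtype=float)
    act_vec = np.array([actual[g] for g in genes], dtype=float)
    correlation: float | None = None
    if n >= 2 and pred_vec.std() > 0 and act_vec.std() > 0:
        correlation = float(stats.pearsonr(pred_vec, act_vec).statistic)
    return AccuracyReport(
        per_gene_pct_diff=pct_diff,
        within_threshold={t: c / n for t, c in within.items()},
        correlation=correlation,
        n_genes=n,
    )


def accuracy_within(
    predicted: Mapping[str, float],
    actual: Mapping[str, float],
    thresholds: list[float],
    jumps: Mapping[str, int] | None = None,
) -> AccuracyReport:
    """Within-threshold accuracy, percent differences, and correlation.

    Only genes present in both maps contribute.  ``thresholds`` are percent
    values; a gene is within threshold ``t`` when
    ``|actual - predicted| <= (t/100) * |predicted|``.  With ``jumps`` given,
    the same metrics are additionally stratified by jump count.
    """
    genes = sorted(set(predicted) & set(actual))
    if not genes:
        raise EvaluationError("predicted and actual share no genes")
    report = _accuracy(genes, predicted, actual, thresholds)
    if jumps is not None:
        by: dict[int, AccuracyReport] = {}
        for j in sorted({jumps[g] for g in genes if g in jumps}):
            sub = [g for g in genes if jumps.get(g) == j]
            if sub:
                by[j] = _accuracy(sub, predicted, actual, thresholds)
        report.by_jumps = by
    return report


@dataclass
class IntraArrayReport:
    mean_duplicate_correlation: float
    mean_ratio_deviation: float  # percent
    n_genes: int
    per_gene_correlation: dict[str, float]
    per_gene_avg_ratio: dict[str, float]


def intra_array_variation(
    matrix: ExpressionMatrix,
    duplicates: list[tuple[str, set[str]]],
) -> IntraArrayReport:
    """Estimate intra-array variation from duplicate-probe genes.

    For each gene with exactly two probes (others are skipped with a
    warning), the two probes' value vectors across arrays give (a) a Pearson
    correlation and (b) a per-array ratio ``probe1/probe2`` whose mean is the
    gene's average ratio.  Probe order is lexicographic by probe id.  The
    report averages correlations over genes and computes
    ``sum(|avg_ratio - 1|) / N * 100`` percent.
    """
    if matrix.n_samples < 3:
        raise EvaluationError("need >= 3 arrays to estimate intra-array variation")
    correlations: dict[str, float] = {}
    avg_ratios: dict[str, float] = {}
    for gene, probes in duplicates:
        if len(probes) != 2:
            logger.warning(
                "gene %s has %d probes (need exactly 2); skipped", gene, len(probes)
            )
            continue
        p1, p2 = sorted(probes)
        v1, v2 = matrix.row(p1), matrix.row(p2)
        if np.any(v2 == 0):
            logger.warning("gene %s probe %s has zero values; skipped", gene, p2)
            continue
        if v1.std() > 0 and v2.std() > 0:
            corr = float(stats.pearsonr(v1, v2).statistic)
        else:
            corr = 1.0 if np.allclose(v1, v2) else 0.0
        correlations[gene] = corr
        avg_ratios[gene] = float(np.mean(v1 / v2))
    if not correlations:
        raise EvaluationError("no usable duplicate-probe genes")
    deviation = float(
        np.mean([abs(r - 1.0) for r in avg_ratios.values()]) * 100.0
    )
    return IntraArrayReport(
        mean_duplicate_correlation=float(np.mean(list(correlations.values()))),
        mean_ratio_deviation=deviation,
        n_genes=len(correlations),
        per_gene_correlation=correlations,
        per_gene_avg_ratio=avg_ratios,
    )
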