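"""Leukocyte signature derivation, ssGSEA composition scoring, naive two-group DE,
and cumulative hypergeometric overlap tests.

The ssGSEA scores of subtype-specific signatures track relative changes in
leukocyte proportions in whole blood; the naive Welch-t differential analysis
is the composition-confounded baseline the REO method is contrasted with.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom, rankdata, ttest_ind
from statsmodels.stats.multitest import multipletests

from refmireo.io_core import ExpressionMatrix, SampleAnnotation, SignatureSet

logger = logging.getLogger(__name__)


@dataclass
class DEStat:
    """Per-feature two-group differential statistic (log2fc = group A minus group B)."""

    feature: str
    log2fc: float
    p_value: float
    fdr: float
    flagged: bool = False


@dataclass
class EnrichmentScoreMatrix:
    """Samples x signatures enrichment scores."""

    sample_ids: list[str]
    signature_names: list[str]
    scores: np.ndarray  # (samples, signatures)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.sample_ids, columns=self.signature_names)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample_id", float_format="%.6g")


@dataclass
class OverlapTestResult:
    """Upper-tail cumulative hypergeometric overlap test."""

    universe_size: int
    set1_size: int
    set2_size: int
    overlap: int
    p_value: float


def _welch_tests(
    a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-row Welch t-test p-values and log2 mean differences (a minus b).

    Rows constant in both groups get p = 1 (no evidence, not an error).
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        res = ttest_ind(a, b, axis=1, equal_var=False)
    pvals = np.asarray(res.pvalue, dtype=float)
    pvals[~np.isfinite(pvals)] = 1.0
    lfc = a.mean(axis=1) - b.mean(axis=1)
    return lfc, pvals


def two_group_de(
    expr: ExpressionMatrix,
    labels: SampleAnnotation,
    lfc_min: float = 0.26,
    fdr_max: float = 0.05,
    group_a: str | None = None,
    group_b: str | None = None,
) -> list[DEStat]:
    """Naive per-feature Welch's t-test on log2 values with BH FDR.

    Features are flagged when |log2fc| >= ``lfc_min`` (default 0.26, a
    1.2-fold change) and FDR <= ``fdr_max``. Direction is the sign of log2fc
    (group A minus group B); by default A, B are the annotation's first two
    group labels in order of appearance.
    """
    groups = labels.group_labels
    if group_a is None or group_b is None:
        if len(groups) != 2:
            raise ValueError(
                f"expected exactly two groups, found {groups}; pass group_a/group_b"
            )
        group_a, group_b = groups
    log_expr = expr.to_log2()
    idx_a = [expr.sample_ids.index(s) for s in labels.samples_in_group(group_a)]
    idx_b = [expr.sample_ids.index(s) for s in labels.samples_in_group(group_b)]
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("both groups need >= 2 samples")
    lfc, pvals = _welch_tests(log_expr.values[:, idx_a], log_expr.values[:, idx_b])
    fdr = multipletests(pvals, method="fdr_bh")[1]
    return [
        DEStat(
            feature=f,
            log2fc=float(l),
            p_value=float(p),
            fdr=float(q),
            flagged=bool(abs(l) >= lfc_min and q <= fdr_max),
        )
        for f, l, p, q in zip(expr.feature_ids, lfc, pvals, fdr)
    ]


def subtype_specific_mirnas(
    expr: ExpressionMatrix,
    ann: SampleAnnotation,
    lfc_min: float = 0.26,
    fdr_max: float = 0.05,
    pairwise: bool = False,
) -> SignatureSet:
    """Derive per-subtype marker signatures by one-vs-rest upregulation.

    For each subtype, Welch's t-test on log2 values against the pooled rest
    (or, with ``pairwise=True``, against every other subtype separately, all
    comparisons required to pass) with BH FDR across features per comparison.
    The signature keeps features with log2fc >= ``lfc_min`` and
    FDR <= ``fdr_max`` — upregulation only. A feature may qualify for more
    than one subtype; overlaps are logged, not forbidden.
    """
    ann.validate_against(expr)
    groups = ann.group_labels
    if len(groups) < 2:
        raise ValueError("need >= 2 subtypes")
    for g in groups:
        if len(ann.samples_in_group(g)) < 2:
            raise ValueError(f"subtype {g!r} has fewer than 2 samples")
    log_expr = expr.to_log2()
    col_idx = {g: [expr.sample_ids.index(s) for s in ann.samples_in_group(g)] for g in groups}
    signatures: dict[str, list[str]] = {}
    assigned: dict[str, list[str]] = {}
    for g in groups:
        own = log_expr.values[:, col_idx[g]]
        if pairwise:
            passes = np.ones(expr.n_features, dtype=bool)
            for other in groups:
                if other == g:
                    continue
                lfc, pvals = _welch_tests(own, log_expr.values[:, col_idx[other]])
                fdr = multipletests(pvals, method="fdr_bh")[1]
                passes &= (lfc >= lfc_min) & (fdr <= fdr_max)
        else:
            rest_idx = [i for gg in groups if gg != g for i in col_idx[gg]]
            lfc, pvals = _welch_tests(own, log_expr.values[:, rest_idx])
            fdr = multipletests(pvals, method="fdr_bh")[1]
            passes = (lfc >= lfc_min) & (fdr <= fdr_max)
        feats = [expr.feature_ids[i] for i in np.flatnonzero(passes)]
        if feats:
            signatures[g] = feats
        for f in feats:
            assigned.setdefault(f, []).append(g)
    overlaps = {f: gs for f, gs in assigned.items() if len(gs) > 1}
    if overlaps:
        logger.info("%d feature(s) qualified for multiple subtypes", len(overlaps))
    return SignatureSet(signatures)


def _ssgsea_one_sample(
    values: np.ndarray, in_set: np.ndarray, alpha: float, order_key: np.ndarray
) -> float:
    """Rank-weighted ECDF-difference step sum for one sample.

    ``order_key`` breaks expression ties deterministically.
    """
    n = values.size
    ranks = rankdata(values)  # ascending, average ties: top feature ~ rank n
    # walk features from highest to lowest expression
    order = np.lexsort((order_key, -values))
    in_ordered = in_set[order]
    w = np.where(in_ordered, ranks[order] ** alpha, 0.0)
    w_total = w.sum()
    n_out = n - int(in_set.sum())
    cum_in = np.cumsum(w) / w_total
    cum_out = np.cumsum(~in_ordered) / n_out if n_out > 0 else np.zeros(n)
    return float(np.sum(cum_in - cum_out))


def ssgsea_scores(
    expr: ExpressionMatrix, signatures: SignatureSet, alpha: float = 0.25
) -> EnrichmentScoreMatrix:
    """Single-sample GSEA enrichment scores (raw, un-normalised).

    Per sample, features are ranked by expression (descending, average ranks
    for ties); in-set steps are weighted by rank^alpha normalised over the
    set, out-set steps are uniform; the score is the sum over the ranked list
    of the weighted in-set ECDF minus the out-set ECDF. Scores depend only on
    within-sample ranks, hence are invariant to per-sample monotone
    transforms.
    """
    sigs = signatures.restricted_to(expr.feature_ids)
    missing = [n for n in signatures.names() if n not in sigs.signatures]
    if missing:
        raise ValueError(f"signature(s) with no feature in the matrix: {missing}")
    if not len(sigs):
        raise ValueError("no usable signatures")
    feat_index = {f: i for i, f in enumerate(expr.feature_ids)}
    order_key = np.arange(expr.n_features)
    masks = {}
    for name in sigs.names():
        mask = np.zeros(expr.n_features, dtype=bool)
        mask[[feat_index[f] for f in sigs[name]]] = True
        masks[name] = mask
    names = sigs.names()
    scores = np.empty((expr.n_samples, len(names)))
    for j in range(expr.n_samples):
        col = expr.values[:, j]
        for k, name in enumerate(names):
            scores[j, k] = _ssgsea_one_sample(col, masks[name], alpha, order_key)
    return EnrichmentScoreMatrix(
        sample_ids=list(expr.sample_ids), signature_names=names, scores=scores
    )


def hypergeometric_overlap(N: int, K: int, n: int, k: int) -> OverlapTestResult:
    """Upper-tail cumulative hypergeometric test P(X >= k), computed in log space.

    X is the overlap of a size-``n`` draw with a size-``K`` subset of a
    size-``N`` universe.
    """
    if K > N or n > N:
        raise ValueError(f"set sizes K={K}, n={n} exceed universe N={N}")
    if k > min(K, n):
        raise ValueError(f"overlap k={k} exceeds min(K, n) = {min(K, n)}")
    if k < 0:
        raise ValueError("overlap k must be non-negative")
    if k == 0:
        p = 1.0
    else:
        xs = np.arange(k, min(K, n) + 1)
        log_terms = hypergeom.logpmf(xs, N, K, n)
        p = float(np.exp(logsumexp(log_terms)))
        p = min(p, 1.0)
    return OverlapTestResult(universe_size=N, set1_size=K, set2_size=n, overlap=k, p_value=p)


def de_stats_to_frame(stats: list[DEStat]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature": [s.feature for s in stats],
            "log2fc": [s.log2fc for s in stats],
            "p_value": [s.p_value for s in stats],
            "fdr": [s.fdr for s in stats],
            "flagged": [s.flagged for s in stats],
        }
    )
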