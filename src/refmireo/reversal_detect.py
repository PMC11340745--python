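"""Detection of disease-associated reversal miRNA pairs, with a label-permutation null.

For each reference stable pair the maintenance of the healthy orientation is
counted in healthy (n1 maintained / m1 not) and disease (n2 / m2) whole-blood
samples; a two-sided Fisher exact test on [[n1, m1], [n2, m2]] plus a
directional delta-P gate identifies pairs whose ordering is lost in disease.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from refmireo.io_core import ExpressionMatrix, SampleAnnotation
from refmireo.reo_core import OrderedPair, StablePairSet

HEALTHY = "healthy"
DISEASE = "disease"


@lru_cache(maxsize=200_000)
def fisher_two_sided(n1: int, m1: int, n2: int, m2: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[n1, m1], [n2, m2]]."""
    return float(fisher_exact([[n1, m1], [n2, m2]], alternative="two-sided")[1])


@dataclass
class PairReversalStat:
    """Per-pair reversal statistics.

    n1/m1 count healthy samples maintaining / not maintaining the reference
    orientation (ties count as not maintained); n2/m2 likewise for disease.
    delta_p = p_healthy - p_disease, positive when the orientation is lost in
    disease.
    """

    pair: OrderedPair
    n1: int
    m1: int
    n2: int
    m2: int
    p_value: float
    fdr: float = float("nan")

    @property
    def p_healthy(self) -> float:
        return self.n1 / (self.n1 + self.m1)

    @property
    def p_disease(self) -> float:
        return self.n2 / (self.n2 + self.m2)

    @property
    def delta_p(self) -> float:
        return self.p_healthy - self.p_disease


def _group_indices(
    expr: ExpressionMatrix, labels: SampleAnnotation, group: str
) -> np.ndarray:
    samples = labels.samples_in_group(group)
    if not samples:
        raise ValueError(f"group {group!r} has zero samples")
    lookup = {s: i for i, s in enumerate(expr.sample_ids)}
    return np.array([lookup[s] for s in samples])


def _maintenance_matrix(
    pairs: StablePairSet, expr: ExpressionMatrix
) -> np.ndarray:
    """Boolean (n_pairs, n_samples): does sample maintain the reference orientation?"""
    feat_index = {f: i for i, f in enumerate(expr.feature_ids)}
    for p in pairs:
        for f in (p.upper, p.lower):
            if f not in feat_index:
                raise ValueError(f"pair member {f!r} absent from expression matrix")
    ui = np.array([feat_index[p.upper] for p in pairs.pairs])
    li = np.array([feat_index[p.lower] for p in pairs.pairs])
    return expr.values[ui, :] > expr.values[li, :]


def _stats_from_counts(
    pairs: StablePairSet, n1: np.ndarray, nh: int, n2: np.ndarray, nd: int
) -> list[PairReversalStat]:
    pvals = np.array(
        [fisher_two_sided(int(a), nh - int(a), int(b), nd - int(b)) for a, b in zip(n1, n2)]
    )
    stats = [
        PairReversalStat(
            pair=p, n1=int(a), m1=nh - int(a), n2=int(b), m2=nd - int(b), p_value=float(pv)
        )
        for p, a, b, pv in zip(pairs.pairs, n1, n2, pvals)
    ]
    if stats:
        fdr = multipletests([s.p_value for s in stats], method="fdr_bh")[1]
        for s, q in zip(stats, fdr):
            s.fdr = float(q)
    return stats


def reversal_stats(
    pairs: StablePairSet,
    expr: ExpressionMatrix,
    labels: SampleAnnotation,
    healthy_label: str = HEALTHY,
    disease_label: str = DISEASE,
) -> list[PairReversalStat]:
    """Fisher exact reversal statistics for every pair, BH-adjusted across all pairs.

    The event counted is expression(upper) > expression(lower); ties count
    toward the complementary event (m). BH correction spans all input pairs —
    the population actually tested.
    """
    hidx = _group_indices(expr, labels, healthy_label)
    didx = _group_indices(expr, labels, disease_label)
    maintained = _maintenance_matrix(pairs, expr)
    n1 = maintained[:, hidx].sum(axis=1)
    n2 = maintained[:, didx].sum(axis=1)
    return _stats_from_counts(pairs, n1, len(hidx), n2, len(didx))


def select_reversals(
    stats: list[PairReversalStat],
    p_healthy_min: float = 0.9,
    delta_min: float = 0.15,
    fdr_max: float = 0.05,
) -> list[PairReversalStat]:
    """Reversal pairs: p_healthy >= 0.9, delta_p >= 0.15, FDR <= 0.05 (boundaries inclusive).

    delta_p is signed, so only loss of the healthy orientation can qualify.
    Output sorted by ascending p-value, then lexicographic pair id.
    """
    selected = [
        s
        for s in stats
        if s.p_healthy >= p_healthy_min and s.delta_p >= delta_min and s.fdr <= fdr_max
    ]
    return sorted(selected, key=lambda s: (s.p_value, s.pair.upper, s.pair.lower))


def permutation_null(
    pairs: StablePairSet,
    expr: ExpressionMatrix,
    labels: SampleAnnotation,
    n_perm: int,
    seed: int,
    healthy_label: str = HEALTHY,
    disease_label: str = DISEASE,
    p_healthy_min: float = 0.9,
    delta_min: float = 0.15,
    fdr_max: float = 0.05,
) -> list[int]:
    """Counts of selected reversal pairs under random label permutations.

    Group sizes are preserved; each permutation reruns the full
    reversal-statistics and selection chain. The pairwise orderings are
    computed once and only the healthy/disease partition is reshuffled, which
    is numerically identical to rerunning from scratch.
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    hidx = _group_indices(expr, labels, healthy_label)
    didx = _group_indices(expr, labels, disease_label)
    all_idx = np.concatenate([hidx, didx])
    nh, nd = len(hidx), len(didx)
    maintained = _maintenance_matrix(pairs, expr)
    rng = np.random.default_rng(seed)
    counts: list[int] = []
    for _ in range(n_perm):
        perm = rng.permutation(all_idx)
        ph, pd_ = perm[:nh], perm[nh:]
        n1 = maintained[:, ph].sum(axis=1)
        n2 = maintained[:, pd_].sum(axis=1)
        stats = _stats_from_counts(pairs, n1, nh, n2, nd)
        selected = select_reversals(
            stats, p_healthy_min=p_healthy_min, delta_min=delta_min, fdr_max=fdr_max
        )
        counts.append(len(selected))
    return counts


def stats_to_frame(
    stats: list[PairReversalStat], selected: list[PairReversalStat] | None = None
) -> pd.DataFrame:
    sel = set(id(s) for s in selected) if selected is not None else None
    rows = []
    for s in stats:
        row = {
            "upper": s.pair.upper,
            "lower": s.pair.lower,
            "n1": s.n1,
            "m1": s.m1,
            "n2": s.n2,
            "m2": s.m2,
            "p_healthy": s.p_healthy,
            "p_disease": s.p_disease,
            "delta_p": s.delta_p,
            "p_value": s.p_value,
            "fdr": s.fdr,
        }
        if sel is not None:
            row["selected"] = id(s) in sel
        rows.append(row)
    return pd.DataFrame(rows)


def write_stats(
    stats: list[PairReversalStat],
    path: str | Path,
    selected: list[PairReversalStat] | None = None,
) -> None:
    stats_to_frame(stats, selected).to_csv(path, sep="\t", index=False, float_format="%.6g")
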