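"""Iterative extraction of differentially expressed miRNAs from reversal pairs.

Each miRNA implicated in a reversal pair is scored by aggregating, over all its
stable-pair partners and all samples, the raw event expression(miRNA) >
expression(partner). The healthy-vs-disease contingency of these events is
tested with Fisher's exact test; the minimum-p miRNA is extracted, its
reversal pairs removed, and the loop repeats until no reversal pairs remain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from refmireo.io_core import ExpressionMatrix, SampleAnnotation
from refmireo.reo_core import OrderedPair, StablePairSet
from refmireo.reversal_detect import (
    DISEASE,
    HEALTHY,
    PairReversalStat,
    _group_indices,
    fisher_two_sided,
)

logger = logging.getLogger(__name__)

UP = "up"
DOWN = "down"


@dataclass
class MiRNAContingency:
    """Aggregated (partner x sample) event counts for one candidate miRNA."""

    mirna: str
    partners: list[str]
    n1: int  # healthy samples x partners with mirna > partner
    m1: int
    n2: int  # disease likewise
    m2: int


@dataclass
class DEMiRNA:
    """An extracted differentially expressed miRNA.

    ``direction`` is disease-vs-healthy: ``down`` when the miRNA out-ranks its
    partners less often in disease (n1*m2 > n2*m1), ``up`` conversely.
    """

    mirna: str
    direction: str
    p_value: float
    q_value: float
    iteration: int
    counts: MiRNAContingency


def mirna_contingency(
    mirna: str,
    pair_universe: StablePairSet,
    expr: ExpressionMatrix,
    labels: SampleAnnotation,
    healthy_label: str = HEALTHY,
    disease_label: str = DISEASE,
) -> MiRNAContingency:
    """Aggregate mirna>partner events over every (partner, sample) combination.

    Partners are all features paired with ``mirna`` in ``pair_universe``
    regardless of orientation; ties count toward the complementary event.
    """
    partners = sorted(pair_universe.partners_of(mirna))
    if not partners:
        raise ValueError(f"{mirna!r} participates in no pair of the pair universe")
    hidx = _group_indices(expr, labels, healthy_label)
    didx = _group_indices(expr, labels, disease_label)
    fi = expr.feature_index(mirna)
    pidx = np.array([expr.feature_index(p) for p in partners])
    above = expr.values[fi, :][None, :] > expr.values[pidx, :]  # (partners, samples)
    n1 = int(above[:, hidx].sum())
    n2 = int(above[:, didx].sum())
    m1 = len(partners) * len(hidx) - n1
    m2 = len(partners) * len(didx) - n2
    return MiRNAContingency(mirna=mirna, partners=partners, n1=n1, m1=m1, n2=n2, m2=m2)


def _direction(c: MiRNAContingency) -> str | None:
    lhs, rhs = c.n1 * c.m2, c.n2 * c.m1
    if lhs > rhs:
        return DOWN
    if lhs < rhs:
        return UP
    return None


def extract_de_mirnas(
    reference_pairs: StablePairSet,
    reversal_pairs: list[PairReversalStat] | list[OrderedPair],
    expr: ExpressionMatrix,
    labels: SampleAnnotation,
    healthy_label: str = HEALTHY,
    disease_label: str = DISEASE,
    universe: str = "reference",
) -> list[DEMiRNA]:
    """Iteratively extract DE miRNAs until the reversal set is exhausted.

    Parameters
    ----------
    reference_pairs
        The filtered reference stable pairs (the counting universe).
    reversal_pairs
        Selected reversal pairs (must be a subset of ``reference_pairs`` as
        unordered pairs); accepts ``PairReversalStat`` or bare pairs.
    universe
        ``"reference"`` (default) counts events over all reference partners of
        a candidate; ``"reversal"`` restricts counting to partners from the
        current reversal set (counts then shrink as pairs are removed).

    Each iteration tests every miRNA in the current reversal set, extracts the
    minimum-p one (ties: more reversal-pair memberships, then lexicographic
    id), assigns its direction by the cross-product rule, and removes its
    reversal pairs. q-values are BH over all extracted miRNAs.
    """
    if universe not in ("reference", "reversal"):
        raise ValueError("universe must be 'reference' or 'reversal'")
    rev: list[OrderedPair] = [
        s.pair if isinstance(s, PairReversalStat) else s for s in reversal_pairs
    ]
    ref_unordered = {p.unordered for p in reference_pairs}
    for p in rev:
        if p.unordered not in ref_unordered:
            raise ValueError(f"reversal pair {p} not among the reference pairs")

    static_universe = universe == "reference"
    cache: dict[str, tuple[MiRNAContingency, float]] = {}

    def score(mirna: str, current_rev: list[OrderedPair]) -> tuple[MiRNAContingency, float]:
        if static_universe and mirna in cache:
            return cache[mirna]
        uni = (
            reference_pairs
            if static_universe
            else StablePairSet(pairs=list(current_rev))
        )
        c = mirna_contingency(
            mirna, uni, expr, labels, healthy_label=healthy_label, disease_label=disease_label
        )
        p = fisher_two_sided(c.n1, c.m1, c.n2, c.m2)
        if static_universe:
            cache[mirna] = (c, p)
        return c, p

    extracted: list[DEMiRNA] = []
    iteration = 0
    while rev:
        membership: dict[str, int] = {}
        for p in rev:
            membership[p.upper] = membership.get(p.upper, 0) + 1
            membership[p.lower] = membership.get(p.lower, 0) + 1
        candidates = sorted(membership)
        scored = [(m, *score(m, rev)) for m in candidates]
        # ascending p, descending reversal membership, lexicographic id
        scored.sort(key=lambda t: (t[2], -membership[t[0]], t[0]))
        chosen: tuple[str, MiRNAContingency, float] | None = None
        for m, c, p in scored:
            if _direction(c) is not None:
                chosen = (m, c, p)
                break
            logger.info("direction undetermined for %s (n1*m2 == n2*m1); skipped", m)
        if chosen is None:
            logger.warning(
                "no candidate with a determinable direction; %d reversal pair(s) left", len(rev)
            )
            break
        mirna, counts, pval = chosen
        iteration += 1
        extracted.append(
            DEMiRNA(
                mirna=mirna,
                direction=_direction(counts),  # type: ignore[arg-type]
                p_value=pval,
                q_value=float("nan"),
                iteration=iteration,
                counts=counts,
            )
        )
        rev = [p for p in rev if mirna not in (p.upper, p.lower)]
    if extracted:
        qvals = multipletests([d.p_value for d in extracted], method="fdr_bh")[1]
        for d, q in zip(extracted, qvals):
            d.q_value = float(q)
    return extracted


def de_to_frame(de: list[DEMiRNA]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mirna": [d.mirna for d in de],
            "dysregulated": [1 if d.direction == UP else -1 for d in de],
            "p_value": [d.p_value for d in de],
            "q_value": [d.q_value for d in de],
            "iteration": [d.iteration for d in de],
            "n1": [d.counts.n1 for d in de],
            "m1": [d.counts.m1 for d in de],
            "n2": [d.counts.n2 for d in de],
            "m2": [d.counts.m2 for d in de],
        }
    )


def write_de(de: list[DEMiRNA], path: str | Path) -> None:
    de_to_frame(de).to_csv(path, sep="\t", index=False, float_format="%.6g")
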