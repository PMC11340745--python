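"""Within-sample relative expression orderings and reference stable-pair mining.

A pair (i, j) is *stable* when expression(i) > expression(j) strictly in every
sample of every purified leukocyte subtype. Because whole blood is a convex
combination of subtype profiles (on the linear scale), a stable ordering can
only reverse in blood if expression changes *within* the cells — which is
exactly the signal the downstream reversal test looks for.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from refmireo.io_core import ExpressionMatrix, SampleAnnotation


@dataclass(frozen=True, order=True)
class OrderedPair:
    """An oriented feature pair; reference orientation expression(upper) > expression(lower)."""

    upper: str
    lower: str

    def __post_init__(self) -> None:
        if self.upper == self.lower:
            raise ValueError(f"pair members must differ, got {self.upper!r} twice")

    @property
    def unordered(self) -> frozenset[str]:
        return frozenset((self.upper, self.lower))


@dataclass
class StablePairSet:
    """A set of oriented pairs stable across reference samples.

    ``p_healthy`` (optional, per pair) is the fraction of healthy whole-blood
    samples maintaining the reference orientation, attached by
    :func:`filter_by_consistency`.
    """

    pairs: list[OrderedPair]
    provenance: list[str] = field(default_factory=list)
    p_healthy: dict[OrderedPair, float] | None = None

    def __post_init__(self) -> None:
        unordered = [p.unordered for p in self.pairs]
        if len(set(unordered)) != len(unordered):
            raise ValueError("pair set contains the same unordered pair twice")
        if self.p_healthy is not None:
            for pair, frac in self.p_healthy.items():
                if not 0.0 <= frac <= 1.0:
                    raise ValueError(f"p_healthy for {pair} outside [0,1]: {frac}")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def __contains__(self, pair: OrderedPair) -> bool:
        return pair in set(self.pairs)

    def features(self) -> set[str]:
        out: set[str] = set()
        for p in self.pairs:
            out.add(p.upper)
            out.add(p.lower)
        return out

    def partners_of(self, feature: str) -> list[str]:
        """All features paired with ``feature``, regardless of orientation."""
        out = []
        for p in self.pairs:
            if p.upper == feature:
                out.append(p.lower)
            elif p.lower == feature:
                out.append(p.upper)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "upper": [p.upper for p in self.pairs],
            "lower": [p.lower for p in self.pairs],
        }
        if self.p_healthy is not None:
            rows["p_healthy"] = [self.p_healthy[p] for p in self.pairs]
        df = pd.DataFrame(rows)
        df["provenance"] = ";".join(self.provenance) if self.provenance else ""
        return df

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def read(cls, path: str | Path) -> "StablePairSet":
        df = pd.read_csv(path, sep="\t", dtype={"upper": str, "lower": str})
        pairs = [OrderedPair(u, l) for u, l in zip(df["upper"], df["lower"])]
        p_healthy = None
        if "p_healthy" in df.columns and not df["p_healthy"].isna().all():
            p_healthy = dict(zip(pairs, df["p_healthy"].astype(float)))
        provenance: list[str] = []
        if "provenance" in df.columns and len(df) and isinstance(df["provenance"].iloc[0], str):
            provenance = [p for p in df["provenance"].iloc[0].split(";") if p]
        return cls(pairs=pairs, provenance=provenance, p_healthy=p_healthy)


def _sorted_pairs(pairs: list[OrderedPair]) -> list[OrderedPair]:
    # lexicographic (upper, lower) for reproducible files
    return sorted(pairs, key=lambda p: (p.upper, p.lower))


def stable_pairs_within(
    expr: ExpressionMatrix,
    ann: SampleAnnotation | None = None,
    per_subtype_mean: bool = False,
    provenance: str | None = None,
) -> StablePairSet:
    """Mine oriented pairs whose ordering holds strictly in every sample.

    Parameters
    ----------
    expr
        Purified-leukocyte expression matrix.
    ann
        Sample-to-subtype annotation. Required only for the
        ``per_subtype_mean`` reading; the default reading ("stable in every
        individual sample of every subtype") uses all samples directly.
    per_subtype_mean
        If True, require the ordering to hold between subtype mean profiles
        instead of every individual sample (less stringent alternative).

    Ties (equal expression) disqualify a pair: a tie anywhere counts as the
    complementary "upper <= lower" event.
    """
    if expr.n_samples == 0 or expr.n_features == 0:
        raise ValueError("empty expression matrix")
    if ann is not None:
        ann.validate_against(expr)
    if per_subtype_mean:
        if ann is None:
            raise ValueError("per_subtype_mean requires a sample annotation")
        cols = []
        for group in ann.group_labels:
            idx = [expr.sample_ids.index(s) for s in ann.samples_in_group(group)]
            cols.append(expr.values[:, idx].mean(axis=1))
        mat = np.column_stack(cols)
    else:
        mat = expr.values

    # greater[i, j] == True iff feature i > feature j in every column
    gt_all = np.all(mat[:, None, :] > mat[None, :, :], axis=2)
    ui, li = np.nonzero(gt_all)
    feats = expr.feature_ids
    pairs = [OrderedPair(feats[u], feats[l]) for u, l in zip(ui, li)]
    prov = [provenance] if provenance else []
    return StablePairSet(pairs=_sorted_pairs(pairs), provenance=prov)


def intersect_stable(a: StablePairSet, b: StablePairSet) -> StablePairSet:
    """Pairs present in both sets with the same orientation; provenance concatenated."""
    b_set = set(b.pairs)
    pairs = [p for p in a.pairs if p in b_set]
    return StablePairSet(pairs=_sorted_pairs(pairs), provenance=a.provenance + b.provenance)


def filter_by_consistency(
    pairs: StablePairSet,
    healthy_expr: ExpressionMatrix,
    min_frac: float = 0.9,
) -> StablePairSet:
    """Retain pairs maintained in >= ``min_frac`` of healthy whole-blood samples.

    The boundary is inclusive: a pair maintained in exactly 90% of samples
    passes ``min_frac=0.9``. Each retained pair is annotated with its observed
    maintenance fraction ``p_healthy``.
    """
    if not 0.0 <= min_frac <= 1.0:
        raise ValueError(f"min_frac must lie in [0,1], got {min_frac}")
    feat_index = {f: i for i, f in enumerate(healthy_expr.feature_ids)}
    for pair in pairs:
        for f in (pair.upper, pair.lower):
            if f not in feat_index:
                raise ValueError(f"pair member {f!r} absent from healthy expression matrix")
    if not len(pairs):
        return StablePairSet(pairs=[], provenance=list(pairs.provenance), p_healthy={})
    ui = np.array([feat_index[p.upper] for p in pairs.pairs])
    li = np.array([feat_index[p.lower] for p in pairs.pairs])
    maintained = healthy_expr.values[ui, :] > healthy_expr.values[li, :]
    frac = maintained.mean(axis=1)
    kept: list[OrderedPair] = []
    p_healthy: dict[OrderedPair, float] = {}
    for pair, f in zip(pairs.pairs, frac):
        if f >= min_frac:
            kept.append(pair)
            p_healthy[pair] = float(f)
    kept = _sorted_pairs(kept)
    return StablePairSet(pairs=kept, provenance=list(pairs.provenance), p_healthy=p_healthy)
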