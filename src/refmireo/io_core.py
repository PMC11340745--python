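"""Shared data model and readers/writers for expression matrices, annotations and signatures.

File conventions: expression matrices are tab-delimited with features in rows
(first column = feature id, header row = sample ids); annotations are TSV with
columns ``sample_id``, ``group`` and optionally ``dataset_id``; signature sets
use the standard GMT dialect (name, description, then feature ids).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_SCALES = ("linear", "log2")


@dataclass
class ExpressionMatrix:
    """A features x samples real-valued expression matrix.

    ``scale`` records whether values are linear intensities or log2 units;
    REO comparisons are invariant to any strictly monotone transform, so the
    scale only matters where fold changes are computed.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: str = "linear"

    def __post_init__(self) -> None:
        self.feature_ids = list(self.feature_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.scale not in VALID_SCALES:
            raise ValueError(f"scale must be one of {VALID_SCALES}, got {self.scale!r}")
        if not self.feature_ids:
            raise ValueError("feature_ids must be non-empty")
        if not self.sample_ids:
            raise ValueError("sample_ids must be non-empty")
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.feature_ids)} features, {len(self.sample_ids)} samples)"
            )
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def feature_index(self, feature: str) -> int:
        try:
            return self._feature_lookup[feature]
        except AttributeError:
            self._feature_lookup = {f: i for i, f in enumerate(self.feature_ids)}
            return self._feature_lookup[feature]

    def sample_index(self, sample: str) -> int:
        return self.sample_ids.index(sample)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(
            feature_ids=self.feature_ids,
            sample_ids=list(sample_ids),
            values=self.values[:, idx],
            scale=self.scale,
        )

    def to_log2(self, pseudocount: float = 0.0) -> "ExpressionMatrix":
        """Return a log2-scale copy (identity if already log2)."""
        if self.scale == "log2":
            return self
        vals = self.values + pseudocount
        if (vals <= 0).any():
            raise ValueError(
                "non-positive linear values cannot be log-transformed; "
                "pass a pseudocount"
            )
        return ExpressionMatrix(
            feature_ids=self.feature_ids,
            sample_ids=self.sample_ids,
            values=np.log2(vals),
            scale="log2",
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)


@dataclass
class SampleAnnotation:
    """Sample-to-group assignment (leukocyte subtype, or healthy/disease)."""

    sample_ids: list[str]
    groups: list[str]
    dataset_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.groups = list(self.groups)
        if len(self.sample_ids) != len(self.groups):
            raise ValueError("sample_ids and groups must have equal length")
        _check_unique(self.sample_ids, "sample")
        if self.dataset_ids is not None:
            self.dataset_ids = list(self.dataset_ids)
            if len(self.dataset_ids) != len(self.sample_ids):
                raise ValueError("dataset_ids length mismatch")

    @property
    def group_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g, None)
        return list(seen)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s, g in zip(self.sample_ids, self.groups) if g == group]

    def group_of(self, sample_id: str) -> str:
        return self.groups[self.sample_ids.index(sample_id)]

    def validate_against(self, expr: ExpressionMatrix) -> None:
        missing = [s for s in self.sample_ids if s not in set(expr.sample_ids)]
        if missing:
            raise ValueError(f"annotated samples absent from expression matrix: {missing}")

    def relabelled(self, groups: Sequence[str]) -> "SampleAnnotation":
        return SampleAnnotation(
            sample_ids=self.sample_ids, groups=list(groups), dataset_ids=self.dataset_ids
        )


@dataclass
class SignatureSet:
    """Named feature lists, one per leukocyte subtype (GMT semantics)."""

    signatures: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, feats in self.signatures.items():
            if len(set(feats)) != len(feats):
                dups = sorted({f for f in feats if feats.count(f) > 1})
                raise ValueError(f"duplicate features in signature {name!r}: {dups}")

    def names(self) -> list[str]:
        return list(self.signatures)

    def __getitem__(self, name: str) -> list[str]:
        return self.signatures[name]

    def __len__(self) -> int:
        return len(self.signatures)

    def restricted_to(self, universe: Iterable[str]) -> "SignatureSet":
        """Drop features outside ``universe``; drop signatures emptied by the filter.

        Both events are logged, not raised, matching warn-and-drop semantics.
        """
        uni = set(universe)
        out: dict[str, list[str]] = {}
        for name, feats in self.signatures.items():
            kept = [f for f in feats if f in uni]
            dropped = len(feats) - len(kept)
            if dropped:
                logger.warning(
                    "signature %s: dropped %d feature(s) outside the universe", name, dropped
                )
            if kept:
                out[name] = kept
            else:
                logger.warning("signature %s empty after filtering; dropped", name)
        return SignatureSet(out)


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for x in ids:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    if dups:
        raise ValueError(f"duplicate {what} ids: {dups}")


def read_expression(
    path: str | Path, scale: str = "linear", impute: bool = False
) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix (features in rows).

    Parameters
    ----------
    path
        TSV file: first column feature ids, header row sample ids.
    scale
        Declared scale of the stored values, ``"linear"`` or ``"log2"``.
    impute
        If True, missing cells are imputed with the feature's row mean;
        default is a hard error (silent missingness corrupts pair counts).
    """
    if scale not in VALID_SCALES:
        raise ValueError(f"scale must be one of {VALID_SCALES}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    feature_ids = [str(f) for f in df.index]
    sample_ids = [str(s) for s in df.columns]
    _check_unique(feature_ids, "feature")
    _check_unique(sample_ids, "sample")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == "":
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(raw)
            except ValueError:
                raise ValueError(
                    f"non-numeric value {raw!r} at feature {feature_ids[i]!r}, "
                    f"sample {sample_ids[j]!r}"
                ) from None
    if np.isnan(values).any():
        if not impute:
            n_missing = int(np.isnan(values).sum())
            raise ValueError(
                f"{n_missing} missing value(s) in {path}; pass impute=True to row-mean impute"
            )
        row_means = np.nanmean(values, axis=1)
        if np.isnan(row_means).any():
            bad = [feature_ids[i] for i in np.flatnonzero(np.isnan(row_means))]
            raise ValueError(f"features with all values missing: {bad}")
        nan_mask = np.isnan(values)
        values[nan_mask] = np.broadcast_to(row_means[:, None], values.shape)[nan_mask]
        logger.warning("imputed %d missing value(s) with row means", int(nan_mask.sum()))
    return ExpressionMatrix(feature_ids, sample_ids, values, scale=scale)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="feature_id", float_format="%.10g")


def read_annotation(path: str | Path) -> SampleAnnotation:
    """Read a sample annotation TSV with columns sample_id, group[, dataset_id]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ValueError(f"annotation file missing required column {col!r}")
    dataset_ids = list(df["dataset_id"]) if "dataset_id" in df.columns else None
    return SampleAnnotation(
        sample_ids=list(df["sample_id"]), groups=list(df["group"]), dataset_ids=dataset_ids
    )


def write_annotation(ann: SampleAnnotation, path: str | Path) -> None:
    data = {"sample_id": ann.sample_ids, "group": ann.groups}
    if ann.dataset_ids is not None:
        data["dataset_id"] = ann.dataset_ids
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> SignatureSet:
    """Read a GMT file: one signature per line, ``name<TAB>description<TAB>features...``."""
    signatures: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"GMT line {lineno}: expected name, description and >=1 feature, "
                    f"got {len(fields)} field(s)"
                )
            name = fields[0]
            feats = [f for f in fields[2:] if f.strip()]
            if not feats:
                raise ValueError(f"GMT line {lineno}: signature {name!r} has no features")
            if name in signatures:
                raise ValueError(f"GMT line {lineno}: duplicate signature name {name!r}")
            signatures[name] = feats
    return SignatureSet(signatures)


def write_gmt(sigs: SignatureSet, path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, feats in sigs.signatures.items():
            fh.write("\t".join([name, description, *feats]) + "\n")


def apply_name_map(expr: ExpressionMatrix, name_map: Mapping[str, str]) -> ExpressionMatrix:
    """Rename features via an old->new mapping table.

    Unmapped features are kept unchanged (count logged). Two features mapping
    to the same new name is an error: merging rows would silently average
    distinct measurements.
    """
    if len(set(name_map)) != len(name_map):  # Mapping keys are unique by construction
        raise ValueError("name map has duplicate old names")
    new_ids = [name_map.get(f, f) for f in expr.feature_ids]
    collisions: dict[str, list[str]] = {}
    seen: dict[str, str] = {}
    for old, new in zip(expr.feature_ids, new_ids):
        if new in seen:
            collisions.setdefault(new, [seen[new]]).append(old)
        else:
            seen[new] = old
    if collisions:
        detail = "; ".join(f"{','.join(olds)}->{new}" for new, olds in sorted(collisions.items()))
        raise ValueError(f"name map collapses distinct features: {detail}")
    n_unmapped = sum(1 for f in expr.feature_ids if f not in name_map)
    if n_unmapped:
        logger.info("%d feature(s) not in name map; kept unchanged", n_unmapped)
    return ExpressionMatrix(
        feature_ids=new_ids,
        sample_ids=expr.sample_ids,
        values=expr.values.copy(),
        scale=expr.scale,
    )
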