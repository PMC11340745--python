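"""End-to-end workflow: stable pairs -> intersection -> consistency filter ->
reversal detection -> iterative DE extraction, with a JSON run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from refmireo import __version__
from refmireo.de_extract import extract_de_mirnas, write_de
from refmireo.io_core import read_annotation, read_expression
from refmireo.reo_core import filter_by_consistency, intersect_stable, stable_pairs_within
from refmireo.reversal_detect import reversal_stats, select_reversals, write_stats

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs, outputs and thresholds for a full pipeline run.

    ``leukocyte_exprs``/``leukocyte_anns`` list one purified reference dataset
    each; stable pairs are mined per dataset and intersected. Thresholds
    default to the method's standard criteria: consistency in >= 90% of
    healthy blood samples, delta-P >= 0.15, FDR <= 0.05.
    """

    leukocyte_exprs: list[str]
    leukocyte_anns: list[str]
    blood_expr: str
    blood_labels: str
    out_dir: str
    scale: str = "log2"
    min_frac: float = 0.9
    p_healthy_min: float = 0.9
    delta_min: float = 0.15
    fdr_max: float = 0.05
    seed: int = 0
    per_subtype_mean: bool = False
    de_universe: str = "reference"
    healthy_label: str = "healthy"
    disease_label: str = "disease"
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if len(self.leukocyte_exprs) != len(self.leukocyte_anns):
            raise ValueError("one annotation per leukocyte expression dataset required")
        if not self.leukocyte_exprs:
            raise ValueError("at least one leukocyte reference dataset required")
        for p in [*self.leukocyte_exprs, *self.leukocyte_anns, self.blood_expr, self.blood_labels]:
            if not Path(p).exists():
                raise FileNotFoundError(p)
        for name in ("min_frac", "p_healthy_min", "delta_min", "fdr_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow, write all artifacts, and return the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    t0 = time.time()

    def stage(name: str):
        logger.info("stage %s (t=%.1fs)", name, time.time() - t0)

    try:
        stage("stable-pairs")
        pair_sets = []
        for expr_path, ann_path in zip(config.leukocyte_exprs, config.leukocyte_anns):
            expr = read_expression(expr_path, scale=config.scale)
            ann = read_annotation(ann_path)
            ps = stable_pairs_within(
                expr, ann, per_subtype_mean=config.per_subtype_mean, provenance=str(expr_path)
            )
            pair_sets.append(ps)
        manifest["stages"]["stable_pairs_per_dataset"] = [len(p) for p in pair_sets]

        stage("intersect")
        reference = pair_sets[0]
        for other in pair_sets[1:]:
            reference = intersect_stable(reference, other)
        manifest["stages"]["pairs_after_intersection"] = len(reference)

        stage("filter-by-consistency")
        blood = read_expression(config.blood_expr, scale=config.scale)
        labels = read_annotation(config.blood_labels)
        healthy = blood.subset_samples(labels.samples_in_group(config.healthy_label))
        filtered = filter_by_consistency(reference, healthy, min_frac=config.min_frac)
        filtered.write(out / "reference_pairs.tsv")
        manifest["stages"]["pairs_after_consistency_filter"] = len(filtered)

        stage("reversal")
        stats = reversal_stats(
            filtered,
            blood,
            labels,
            healthy_label=config.healthy_label,
            disease_label=config.disease_label,
        )
        reversals = select_reversals(
            stats,
            p_healthy_min=config.p_healthy_min,
            delta_min=config.delta_min,
            fdr_max=config.fdr_max,
        )
        write_stats(stats, out / "reversal_stats.tsv", selected=reversals)
        manifest["stages"]["reversal_pairs"] = len(reversals)

        stage("de")
        de = extract_de_mirnas(
            filtered,
            reversals,
            blood,
            labels,
            healthy_label=config.healthy_label,
            disease_label=config.disease_label,
            universe=config.de_universe,
        )
        write_de(de, out / "de_mirnas.tsv")
        manifest["stages"]["de_mirnas"] = len(de)
    except Exception as exc:
        manifest["failed_stage"] = _current_stage(manifest)
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed at stage {manifest['failed_stage']}: {exc}") from exc

    manifest["runtime_seconds"] = round(time.time() - t0, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _current_stage(manifest: dict) -> str:
    order = [
        "stable_pairs_per_dataset",
        "pairs_after_intersection",
        "pairs_after_consistency_filter",
        "reversal_pairs",
        "de_mirnas",
    ]
    names = ["stable-pairs", "intersect", "filter-by-consistency", "reversal", "de"]
    done = manifest.get("stages", {})
    for key, name in zip(order, names):
        if key not in done:
            return name
    return "finalize"
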