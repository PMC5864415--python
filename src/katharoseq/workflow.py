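"""End-to-end QC: composition -> fits -> LOD -> threshold -> exclusion.

:func:`run_qc` is the library entry point behind ``katharoseq run``.  It
reads a feature table and control-annotated sample map, fits the Hill
curve in both the cells and reads variables, determines limits of
detection for composition and depth, derives the exclusion threshold with
the configured strategy, applies it to every sample, and writes:

* ``decisions.tsv`` — one row per sample (depth, threshold, verdict);
* ``summary.json`` — the stable machine-readable report (thresholds,
  fits, LOD tables, success rates, contamination summary);
* ``filtered_table.<ext>`` — the retained samples, counts untouched;
* per-metric LOD tables as TSV.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, Optional

from . import __version__
from .composition import composition_points
from .data_model import (
    NEGATIVE_CLASSES,
    POSITIVE_CLASSES,
    FeatureTable,
    StudyDesign,
    TargetSpec,
    read_feature_table,
    read_metadata,
    write_feature_table,
)
from .detection import limit_of_detection
from .errors import MissingControlsError, ValidationError
from .exclusion import (
    RECOMMENDED_DESIGN,
    ReadCountFilter,
    contamination_report,
    success_rate,
)
from .hill import fit_hill

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one QC run."""

    table: str
    metadata: str
    out_dir: str
    format: str = "tsv"
    target_spec: Optional[TargetSpec] = None
    strategy: str = "max_input_median"
    threshold: Optional[float] = None
    alpha: float = 0.05
    ymax_mode: str = "free"
    seed: Optional[int] = None
    quiet: bool = False


def _resolve_target_spec(config: RunConfig, design: StudyDesign) -> Optional[TargetSpec]:
    if config.target_spec is not None:
        return config.target_spec
    for rec in design.records.values():
        if rec.control_class in POSITIVE_CLASSES and rec.target_spec is not None:
            return rec.target_spec
    return None


def run_qc(config: RunConfig) -> Dict:
    """Execute the full QC pipeline; returns the summary dictionary."""
    table = read_feature_table(config.table, format=config.format)
    design = read_metadata(config.metadata)
    unknown = set(table.sample_ids) - set(design.records)
    if unknown:
        raise ValidationError(
            f"samples present in table but absent from metadata: {sorted(unknown)[:5]}"
        )
    target_spec = _resolve_target_spec(config, design)

    pos_points, pos_zero = composition_points(
        table, design, {"extraction_positive"}, target_spec=target_spec
    )
    neg_points, neg_zero = composition_points(
        table, design, NEGATIVE_CLASSES, target_spec=target_spec
    )
    if not pos_points and config.strategy != "fixed":
        raise MissingControlsError(
            "no usable extraction positive controls; a KatharoSeq-style run "
            "needs " + RECOMMENDED_DESIGN
        )

    summary: Dict = {
        "version": __version__,
        "config": {
            "strategy": config.strategy,
            "alpha": config.alpha,
            "ymax_mode": config.ymax_mode,
            "target_spec": str(target_spec) if target_spec is not None else None,
            "seed": config.seed,
        },
        "n_samples": table.n_samples,
        "n_features": table.n_features,
        "zero_depth_controls": sorted(pos_zero + neg_zero),
    }

    cells_fit = reads_fit = None
    if target_spec is not None and len(pos_points) >= 2:
        distinct = {p.input_cells for p in pos_points}
        ymax_mode = config.ymax_mode if len(distinct) >= 3 else "fixed_1"
        cells_fit = fit_hill(
            [(p.input_cells, p.target_fraction) for p in pos_points],
            ymax_mode=ymax_mode,
            x_variable="cells",
        )
        reads_fit = fit_hill(
            [(p.depth, p.target_fraction) for p in pos_points],
            ymax_mode=ymax_mode,
            x_variable="reads",
        )
        summary["cells_fit"] = json.loads(cells_fit.to_json())
        summary["reads_fit"] = json.loads(reads_fit.to_json())

    lods = {}
    if len(neg_points) >= 2 and len({p.input_cells for p in pos_points}) >= 2:
        for metric in ("target_fraction", "depth"):
            result = limit_of_detection(
                pos_points, neg_points, metric=metric, alpha=config.alpha
            )
            lods[metric] = result
            summary.setdefault("lod", {})[metric] = json.loads(result.to_json())

    filt = ReadCountFilter(
        strategy=config.strategy,
        threshold=config.threshold,
        target_spec=target_spec,
        ymax_mode=config.ymax_mode,
    )
    filtered = filt.fit_transform(table, design)
    decisions = filt.decisions_
    summary["threshold"] = filt.threshold_
    summary["strategy"] = config.strategy
    summary["n_retained"] = sum(d.retained for d in decisions)
    summary["n_excluded"] = len(decisions) - summary["n_retained"]

    rates = {}
    for label, classes in (
        ("samples", {"sample"}),
        ("extraction_positive", {"extraction_positive"}),
        ("negatives", NEGATIVE_CLASSES),
    ):
        ids = design.sample_ids_of_class(classes)
        ids = [s for s in ids if s in set(table.sample_ids)]
        if ids:
            rates[label] = success_rate(decisions, ids)
    summary["success_rates"] = rates

    if cells_fit is not None and cells_fit.converged and target_spec is not None:
        report = contamination_report(table, design, target_spec, cells_fit)
        summary["contamination"] = asdict(report)

    _write_outputs(config, summary, decisions, filtered, lods)
    return summary


def _write_outputs(config: RunConfig, summary, decisions, filtered, lods) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "decisions.tsv", "w") as fh:
        fh.write("sample_id\tdepth\tthreshold\tretained\tstrategy\n")
        for d in decisions:
            fh.write(
                f"{d.sample_id}\t{d.depth}\t{d.threshold:g}\t{d.retained}\t{d.strategy}\n"
            )
    ext = "biom" if config.format == "biom" else "tsv"
    write_feature_table(filtered, out / f"filtered_table.{ext}", format=config.format)
    for metric, result in lods.items():
        with open(out / f"lod_{metric}.tsv", "w") as fh:
            fh.write(result.to_tsv())
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, sort_keys=True, indent=2)
        fh.write("\n")
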