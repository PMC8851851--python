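"""End-to-end orchestration: simulate/read -> normalize -> classify -> report.

A run is described by a flat key-value config (YAML mapping, one level).
Cascade threshold keys are recognized by name and forwarded to
:class:`contactnorm.cascade.CascadeConfig`; unknown keys are errors so that
a mistyped threshold cannot silently fall back to a default. The effective
config is echoed into the output directory, and a failed stage removes the
partial outputs it wrote.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Optional

import yaml

from .annotate import location_summary, neighborhood_by_layer, read_annotations, read_edges
from .cascade import CascadeConfig, run_cascade
from .io import read_expression, write_classification
from .quantify import tpm_normalize
from .simulate import evaluate_recovery, generate_dataset, study_mix

logger = logging.getLogger(__name__)

_CASCADE_KEYS = {f.name for f in fields(CascadeConfig)}


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    out_dir: str = "contactnorm_run"
    seed: int = 0
    # input tables; when counts is None a dataset is simulated
    counts: Optional[str] = None
    lengths: Optional[str] = None
    design: Optional[str] = None
    truth: Optional[str] = None
    annotations: Optional[str] = None
    edges: Optional[str] = None
    focus: Optional[str] = None
    min_score: float = 0.400
    # simulation parameters (used when counts is None)
    simulate_scale: float = 0.02
    simulate_replicates: int = 3
    simulate_library_size: float = 2e7
    cascade: CascadeConfig = field(default_factory=CascadeConfig)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        run_keys = {f.name for f in fields(cls)} - {"cascade"}
        unknown = set(mapping) - run_keys - _CASCADE_KEYS
        if unknown:
            raise ValueError(
                f"unknown config key(s) {sorted(unknown)}; "
                f"known: {sorted(run_keys | _CASCADE_KEYS)}"
            )
        cascade = CascadeConfig.from_mapping(
            {k: v for k, v in mapping.items() if k in _CASCADE_KEYS}
        )
        run = {k: v for k, v in mapping.items() if k in run_keys}
        return cls(cascade=cascade, **run)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            mapping = yaml.safe_load(handle) or {}
        if not isinstance(mapping, dict):
            raise ValueError(f"{path}: config must be a flat key-value mapping")
        return cls.from_mapping(mapping)

    def to_flat_dict(self) -> dict:
        out = asdict(self)
        out.update(out.pop("cascade"))
        return out


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the machine-readable run summary."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _path(name: str) -> Path:
        p = out_dir / name
        written.append(p)
        return p

    try:
        logger.info("run-all: seed=%d out_dir=%s", config.seed, out_dir)
        with open(_path("config_used.yaml"), "w") as handle:
            yaml.safe_dump(config.to_flat_dict(), handle, sort_keys=True)

        truth = None
        if config.counts is not None:
            if config.lengths is None or config.design is None:
                raise ValueError("counts input requires lengths and design paths")
            matrix, design = read_expression(config.counts, config.lengths, config.design)
            if config.truth is not None:
                import pandas as pd
                truth = pd.read_csv(config.truth, sep="\t", index_col="gene_id")
            logger.info("input: %d genes x %d samples from %s",
                        *matrix.values.shape, config.counts)
        else:
            dataset = generate_dataset(
                study_mix(scale=config.simulate_scale),
                replicates=config.simulate_replicates,
                library_size=config.simulate_library_size,
                seed=config.seed,
            )
            dataset.write(out_dir)
            written += [out_dir / n for n in
                        ("counts.tsv", "lengths.tsv", "design.tsv", "truth.tsv")]
            matrix, design, truth = dataset.to_expression_matrix(), dataset.design, dataset.truth
            logger.info("simulated: %d genes x %d samples (scale %g)",
                        *matrix.values.shape, config.simulate_scale)

        tpm = tpm_normalize(matrix)
        tpm.write(_path("tpm.tsv"))

        result = run_cascade(tpm, design, config.cascade)
        write_classification(result.per_gene, _path("classification.tsv"))
        summary: dict = {"onion": result.summary, "seed": config.seed,
                         "thresholds": config.cascade.to_dict()}

        if config.annotations is not None:
            annotations = read_annotations(config.annotations)
            table = location_summary(result.per_gene, annotations)
            table.to_csv(_path("location_summary.tsv"), sep="\t")
            if config.edges is not None and config.focus is not None:
                edges = read_edges(config.edges)
                by_layer = neighborhood_by_layer(
                    edges, config.focus, result.per_gene, config.min_score)
                summary["neighborhood"] = {
                    "focus": config.focus,
                    "min_score": config.min_score,
                    "by_layer": by_layer.to_dict(),
                }

        if truth is not None:
            report = evaluate_recovery(truth, result.per_gene)
            summary["recovery"] = report.to_dict()

        with open(_path("summary.json"), "w") as handle:
            json.dump(summary, handle, indent=2, sort_keys=True)
        logger.info("run-all: wrote %s", out_dir / "summary.json")
        return summary
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
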