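"""One-config orchestration of the full workflow.

Stages run in order: DMP -> DMR -> enrichment -> differential expression
-> concordance -> replication.  Stages whose inputs are not configured are
skipped with a logged notice; a stage failure aborts the run naming the
stage.  Every output table is written deterministically (no timestamps)
so a rerun with the same config and seed is byte-identical; the run
manifest records package/library versions, the seed and input checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .array_io import (
    read_beta_matrix,
    read_gmt,
    read_manifest,
    read_probe_list,
    read_sample_sheet,
    write_dmr_bed,
    write_table,
)
from .compare import intersect_universe, replicate
from .dmp import call_dmps, dmps_to_frame, sample_pca, summarize_dmps, volcano_table
from .dmr import DMRParams, call_dmrs, dmrs_to_frame, windows_to_frame
from .enrichment import enrich, enrichment_to_frame
from .expression import concordance_table, differential_expression

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "ConfigError", "StageError", "run_pipeline"]


class ConfigError(ValueError):
    """The configuration violates its schema."""


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


@dataclass
class AnalysisConfig:
    betas: str
    samples: str
    manifest: str
    gmt: str | None = None
    expr: str | None = None
    expr_samples: str | None = None
    universe: str | None = None
    betas2: str | None = None
    samples2: str | None = None
    manifest_dialect: str = "generic"
    dmp_p: float = 0.001
    dmr_p: float = 0.001
    min_abs_delta: float = 0.3
    effect_threshold: float = 0.15
    enrich_p: float = 0.05
    de_p: float = 0.05
    window_size: int = 3
    expr_scale: str = "auto"
    seed: int = 0

    def __post_init__(self):
        for name in ("dmp_p", "dmr_p", "min_abs_delta", "effect_threshold", "enrich_p", "de_p"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ConfigError(f"thresholds.{name}: must be in (0, 1], got {v}")
        if self.window_size < 2:
            raise ConfigError(f"window_size: must be >= 2, got {self.window_size}")
        for name in ("betas", "samples", "manifest"):
            if not getattr(self, name):
                raise ConfigError(f"paths.{name}: required")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        flat: dict = {}
        flat.update(raw.get("paths", {}) or {})
        flat.update(raw.get("thresholds", {}) or {})
        for key, value in raw.items():
            if key not in ("paths", "thresholds"):
                flat[key] = value
        known = set(cls.__dataclass_fields__)
        unknown = set(flat) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        try:
            return cls(**flat)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: AnalysisConfig, out_dir) -> dict:
    """Run all configured stages under ``out_dir``; returns the report dict
    (also written as run_manifest.json alongside the stage tables)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "seed": config.seed}
    current_stage = "load"
    try:
        # ---- load -------------------------------------------------------
        annotations = read_manifest(config.manifest, dialect=config.manifest_dialect)
        ann_map = {a.probe_id: a for a in annotations}
        matrix = read_beta_matrix(config.betas, config.samples)
        report["stages"]["load"] = {
            "n_probes": len(matrix.probe_ids),
            "n_samples": len(matrix.sample_ids),
        }

        # ---- dmp --------------------------------------------------------
        current_stage = "dmp"
        dmps = call_dmps(matrix, ann_map, p_threshold=config.dmp_p)
        summary = summarize_dmps(dmps, config.dmp_p, config.effect_threshold)
        write_table(dmps_to_frame(dmps), out / "dmps.tsv")
        write_table(volcano_table(dmps, config.dmp_p), out / "volcano.tsv")
        coords, frac = sample_pca(matrix, n_components=min(2, len(matrix.sample_ids) - 1))
        coords = coords.reset_index()
        for i, f in enumerate(frac):
            coords[f"variance_fraction_PC{i + 1}"] = f
        write_table(coords, out / "pca.tsv")
        with open(out / "summary.json", "w") as fh:
            json.dump(summary.__dict__, fh, indent=2, sort_keys=True)
        report["stages"]["dmp"] = {"n_significant": summary.n_significant}

        # ---- dmr --------------------------------------------------------
        current_stage = "dmr"
        params = DMRParams(
            window_size=config.window_size,
            p_threshold=config.dmr_p,
            min_abs_delta=config.min_abs_delta,
        )
        windows, dmrs = call_dmrs(matrix, annotations, params)
        write_table(windows_to_frame(windows), out / "windows.tsv")
        write_table(dmrs_to_frame(dmrs), out / "dmrs.tsv")
        write_dmr_bed(dmrs, out / "dmrs.bed")
        report["stages"]["dmr"] = {"n_windows": len(windows), "n_dmrs": len(dmrs)}

        # ---- enrich -----------------------------------------------------
        current_stage = "enrich"
        gene_lists = {
            "hyper": {
                g
                for d in dmps
                if d.significant and d.delta > 0 and d.annotation
                for g in d.annotation.genes
            },
            "hypo": {
                g
                for d in dmps
                if d.significant and d.delta < 0 and d.annotation
                for g in d.annotation.genes
            },
            "dmr": {g for r in dmrs for g in r.genes},
        }
        if config.gmt:
            library = read_gmt(config.gmt)
            counts = {}
            for label, genes in gene_lists.items():
                results = enrich(sorted(genes), library, p_cut=config.enrich_p, seed=config.seed)
                write_table(enrichment_to_frame(results), out / f"enrich_{label}.tsv")
                counts[label] = len(results)
            report["stages"]["enrich"] = counts
        else:
            logger.info("stage 'enrich' skipped: no gmt configured")
            report["stages"]["enrich"] = "skipped"

        # ---- de + concord ----------------------------------------------
        if config.expr and config.expr_samples:
            current_stage = "de"
            expr = pd.read_csv(config.expr, sep="\t", index_col=0)
            expr_groups = read_sample_sheet(config.expr_samples)
            meth_genes = sorted(set().union(*gene_lists.values()))
            de = differential_expression(
                expr, expr_groups, genes=meth_genes, scale=config.expr_scale
            )
            write_table(de, out / "de.tsv")
            report["stages"]["de"] = {
                "n_tested": len(de),
                "n_significant": int((de["p_value"] < config.de_p).sum()) if len(de) else 0,
            }

            current_stage = "concord"
            directions: dict = {}
            for d in dmps:
                if d.significant and d.annotation:
                    for g in d.annotation.genes:
                        directions[g] = d.direction
            for r in dmrs:
                if r.direction in ("HYPER", "HYPO"):
                    for g in r.genes:
                        directions[g] = r.direction
            table = concordance_table(directions, de, de_p=config.de_p)
            write_table(table, out / "concordance.tsv")
            report["stages"]["concord"] = {
                "n_joined": len(table),
                "n_de_significant": int(table["de_significant"].sum()) if len(table) else 0,
            }
        else:
            logger.info("stages 'de'/'concord' skipped: no expression data configured")
            report["stages"]["de"] = report["stages"]["concord"] = "skipped"

        # ---- compare ----------------------------------------------------
        if config.universe and config.betas2 and config.samples2:
            current_stage = "compare"
            universe = read_probe_list(config.universe)
            betas2 = read_beta_matrix(config.betas2, config.samples2)
            sig = [d for d in dmps if d.significant]
            subset = intersect_universe([d.probe_id for d in sig], universe)
            rep = replicate(
                subset,
                betas2,
                {d.probe_id: d.delta for d in sig},
                strict_p=config.dmp_p,
                n_input=len(sig),
            )
            write_table(rep.records, out / "replication.tsv")
            report["stages"]["compare"] = {
                "n_input": rep.n_input,
                "n_in_universe": rep.n_in_universe,
                "n_strict": rep.n_replicated_strict,
                "n_loose": rep.n_replicated_loose,
                "n_concordant": rep.n_concordant_direction,
            }
        else:
            logger.info("stage 'compare' skipped: no second dataset configured")
            report["stages"]["compare"] = "skipped"
    except (StageError, ConfigError):
        raise
    except Exception as exc:
        raise StageError(f"stage {current_stage!r} failed: {exc}") from exc

    import numpy
    import scipy

    report["versions"] = {
        "wsmeth": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
    }
    inputs = {
        k: str(getattr(config, k))
        for k in (
            "betas",
            "samples",
            "manifest",
            "gmt",
            "expr",
            "expr_samples",
            "universe",
            "betas2",
            "samples2",
        )
        if getattr(config, k)
    }
    report["input_checksums"] = {k: _sha256(v) for k, v in inputs.items()}
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
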