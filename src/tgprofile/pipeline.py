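"""Configuration, orchestration and reproducibility glue.

Binds the stages ``simulate -> qc/process -> enrich -> analyze`` into one
run driven by a YAML config with a single master seed.  Every stochastic
stage derives its own seed deterministically from the master seed and the
stage name, so a run is reproducible end to end while stages stay
decorrelated.  A manifest (config hash, input checksums, per-stage record
counts and timings) is written atomically at the end of a run.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrichment import (
    CountTable,
    heatmap_consensus,
    logo_matrix,
    peptide_ef,
    position_aa_ef,
    rank_top,
    write_consensus_json,
)
from .importance import (
    fit_rf_cv,
    hydrophobic_count_analysis,
    hypertune,
    one_hot_encode,
    permutation_importance_cv,
    polarity_by_position,
)
from .library_design import LibraryDesign, load_design, load_preset
from .read_processing import count_peptides, write_qc_json
from .simulate import (
    SelectionModel,
    SequencingModel,
    default_selection_model,
    simulate_experiment,
)

logger = logging.getLogger("tgprofile")

__all__ = [
    "ConfigError",
    "RunConfig",
    "derive_seed",
    "run_all",
    "validate_config",
]


class ConfigError(ValueError):
    """Aggregated configuration problems; ``errors`` lists them all."""

    def __init__(self, errors: list[str]):
        super().__init__("; ".join(errors))
        self.errors = errors


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


_DEFAULTS: dict = {
    "design": "Lib4",
    "outdir": "tgprofile_run",
    "seed": 0,
    "log_level": "INFO",
    "simulate": {
        "enabled": True,
        "n_molecules": 20_000,
        "reads_per_sample": 50_000,
        "per_base_error": 0.005,
        "mean_quality": 35.0,
        "quality_sd": 3.0,
        "read_length": None,
        "gzip": False,
        "model": {
            "baseline": -2.0,
            "background_rate": 0.002,
            "weights": {},
            "requires_reactive_gln": True,
            "artifact_motif": None,
            "artifact_boost": 0.0,
            "use_default_weights": True,
        },
    },
    "process": {
        "quality_threshold": 25.0,
        "tag_mismatch": 1,
        "anchor_mismatch": 1,
        "adapters": [],
        "inputs": {},
    },
    "enrich": {
        "min_count_after": 100,
        "top_n": 100,
        "pseudocount": 0.0,
    },
    "analyze": {
        "enabled": True,
        "folds": 10,
        "repeats": 10,
        "n_estimators": 200,
        "hypertune_iters": 0,
        "min_count_before": 1,
        "max_peptides": None,
        "log_response": False,
        "alpha": 0.01,
        "rf_params": {},
    },
}


@dataclass
class RunConfig:
    """Normalized run configuration (defaults filled, paths resolved)."""

    design: str
    outdir: Path
    seed: int
    log_level: str
    simulate: dict
    process: dict
    enrich: dict
    analyze: dict
    base_dir: Path = field(default_factory=Path.cwd)

    def to_dict(self) -> dict:
        return {
            "design": self.design,
            "outdir": str(self.outdir),
            "seed": self.seed,
            "log_level": self.log_level,
            "simulate": self.simulate,
            "process": self.process,
            "enrich": self.enrich,
            "analyze": self.analyze,
        }

    def config_hash(self) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()

    def load_design(self) -> LibraryDesign:
        if self.design.lower() in ("libq", "lib4"):
            return load_preset(self.design)
        return load_design(self.base_dir / self.design)


def _merge_defaults(doc: dict, defaults: dict, prefix: str, errors: list[str]):
    out = {}
    for key, default in defaults.items():
        if key in doc:
            value = doc[key]
            if isinstance(default, dict) and key not in (
                "inputs",
                "weights",
                "rf_params",
            ):
                if not isinstance(value, dict):
                    errors.append(f"{prefix}{key}: expected a mapping")
                    value = default
                else:
                    value = _merge_defaults(
                        value, default, f"{prefix}{key}.", errors
                    )
            out[key] = value
        else:
            out[key] = default
    for key in doc:
        if key not in defaults:
            hint = difflib.get_close_matches(key, defaults.keys(), n=1)
            msg = f"{prefix}{key}: unknown key"
            if hint:
                msg += f" (did you mean {hint[0]!r}?)"
            errors.append(msg)
    return out


def _check_ranges(cfg: dict, errors: list[str]) -> None:
    sim, proc, enr, ana = (
        cfg["simulate"],
        cfg["process"],
        cfg["enrich"],
        cfg["analyze"],
    )
    if proc["quality_threshold"] < 0:
        errors.append("process.quality_threshold: must be >= 0")
    if proc["tag_mismatch"] < 0:
        errors.append("process.tag_mismatch: must be >= 0")
    if proc["anchor_mismatch"] < 0:
        errors.append("process.anchor_mismatch: must be >= 0")
    if enr["min_count_after"] < 0:
        errors.append("enrich.min_count_after: must be >= 0")
    if enr["pseudocount"] < 0:
        errors.append("enrich.pseudocount: must be >= 0")
    if sim["enabled"]:
        if sim["n_molecules"] < 1:
            errors.append("simulate.n_molecules: must be >= 1")
        if sim["reads_per_sample"] < 1:
            errors.append("simulate.reads_per_sample: must be >= 1")
        if not 0 <= sim["per_base_error"] < 1:
            errors.append("simulate.per_base_error: must be in [0, 1)")
        if not 0 <= sim["model"]["background_rate"] < 1:
            errors.append("simulate.model.background_rate: must be in [0, 1)")
    if ana["folds"] < 2:
        errors.append("analyze.folds: must be >= 2")
    if ana["repeats"] < 1:
        errors.append("analyze.repeats: must be >= 1")


def validate_config(path) -> RunConfig:
    """Load, default-fill and validate a YAML run config.

    All problems are aggregated into a single :class:`ConfigError` rather
    than reported one at a time.
    """
    path = Path(path)
    errors: list[str] = []
    if not path.exists():
        raise ConfigError([f"config file not found: {path}"])
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigError([f"{path}: config must be a mapping"])
    cfg = _merge_defaults(doc, _DEFAULTS, "", errors)
    _check_ranges(cfg, errors)
    base = path.parent.resolve()
    run = RunConfig(
        design=str(cfg["design"]),
        outdir=(base / cfg["outdir"]).resolve(),
        seed=int(cfg["seed"]),
        log_level=str(cfg["log_level"]),
        simulate=cfg["simulate"],
        process=cfg["process"],
        enrich=cfg["enrich"],
        analyze=cfg["analyze"],
        base_dir=base,
    )
    if not cfg["simulate"]["enabled"]:
        try:
            design = run.load_design()
        except Exception as exc:  # design errors reported with the rest
            errors.append(f"design: {exc}")
            design = None
        inputs = cfg["process"]["inputs"] or {}
        need = (
            {"r1", "r2"}
            if design is not None and design.tags
            else {"before_r1", "before_r2", "after_r1", "after_r2"}
        )
        missing = need - set(inputs)
        if missing:
            errors.append(
                "process.inputs: simulation disabled but input FASTQ "
                f"missing: {sorted(missing)}"
            )
        for key, value in inputs.items():
            if not (base / value).exists():
                errors.append(f"process.inputs.{key}: file not found: {value}")
    else:
        try:
            run.load_design()
        except Exception as exc:
            errors.append(f"design: {exc}")
    if errors:
        raise ConfigError(errors)
    return run


def _selection_model(cfg: dict) -> SelectionModel:
    if cfg.get("use_default_weights") and not cfg.get("weights"):
        base = default_selection_model()
        weights = base.weights
    else:
        weights = {
            int(rel): {str(a): float(w) for a, w in row.items()}
            for rel, row in (cfg.get("weights") or {}).items()
        }
    boost = None
    if cfg.get("artifact_motif"):
        boost = (str(cfg["artifact_motif"]), float(cfg["artifact_boost"]))
    return SelectionModel(
        weights=weights,
        baseline=float(cfg["baseline"]),
        background_rate=float(cfg["background_rate"]),
        artifact_boost=boost,
        requires_reactive_gln=bool(cfg["requires_reactive_gln"]),
    )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _atomic_write_json(doc: dict, path: Path) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
    os.replace(tmp, path)


class StageFailure(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage


def run_all(config: RunConfig) -> dict:
    """Run every enabled stage and return the manifest."""
    t_all = time.perf_counter()
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    design = config.load_design()
    manifest: dict = {
        "tool_version": __version__,
        "config_hash": config.config_hash(),
        "design": design.name,
        "stages": {},
        "inputs": {},
    }

    # --- simulate -------------------------------------------------------
    if config.simulate["enabled"]:
        stage_t = time.perf_counter()
        try:
            sim_cfg = config.simulate
            seq_model = SequencingModel(
                reads_per_sample=int(sim_cfg["reads_per_sample"]),
                read_length=sim_cfg["read_length"],
                per_base_error=float(sim_cfg["per_base_error"]),
                mean_quality=float(sim_cfg["mean_quality"]),
                quality_sd=float(sim_cfg["quality_sd"]),
            )
            model = _selection_model(sim_cfg["model"])
            sim = simulate_experiment(
                design,
                model,
                seq_model,
                int(sim_cfg["n_molecules"]),
                outdir / "sim",
                derive_seed(config.seed, "simulate"),
                gzip_output=bool(sim_cfg["gzip"]),
            )
            truth = sim.truth_table().sort_values("peptide", kind="mergesort")
            truth.to_csv(outdir / "sim" / "truth.tsv", sep="\t", index=False)
            fastq = sim.fastq_paths
        except Exception as exc:
            raise StageFailure("simulate", exc) from exc
        manifest["stages"]["simulate"] = {
            "n_molecules": int(config.simulate["n_molecules"]),
            "n_species": int(len(sim.pool)),
            "seconds": round(time.perf_counter() - stage_t, 3),
        }
        logger.info("[simulate] %d distinct molecules", len(sim.pool))
    else:
        inputs = config.process["inputs"]
        if design.tags:
            fastq = {
                "tagged": (
                    str(config.base_dir / inputs["r1"]),
                    str(config.base_dir / inputs["r2"]),
                )
            }
        else:
            fastq = {
                "before": (
                    str(config.base_dir / inputs["before_r1"]),
                    str(config.base_dir / inputs["before_r2"]),
                ),
                "after": (
                    str(config.base_dir / inputs["after_r1"]),
                    str(config.base_dir / inputs["after_r2"]),
                ),
            }

    for sample, (r1, r2) in fastq.items():
        manifest["inputs"][sample] = {
            "r1": {"path": r1, "sha256": _sha256(r1)},
            "r2": {"path": r2, "sha256": _sha256(r2)},
        }

    # --- process --------------------------------------------------------
    stage_t = time.perf_counter()
    try:
        proc = config.process
        kwargs = dict(
            quality_threshold=float(proc["quality_threshold"]),
            tag_mismatch=int(proc["tag_mismatch"]),
            anchor_mismatch=int(proc["anchor_mismatch"]),
            adapters=tuple(proc["adapters"]),
        )
        if design.tags:
            (r1, r2) = next(iter(fastq.values()))
            counts, qc = count_peptides(r1, r2, design, **kwargs)
        else:
            from collections import Counter

            from .read_processing import ProcessedCounts, QCReport

            counts = ProcessedCounts()
            qc = QCReport()
            for sample, (r1, r2) in fastq.items():
                part, part_qc = count_peptides(
                    r1, r2, design, sample_label=sample, **kwargs
                )
                counts.counts[sample] = part.counts.get(sample, Counter())
                counts.rejections += part.rejections
                counts.n_pairs += part.n_pairs
                for attr in (
                    "n_reads",
                    "n_bases",
                    "n_q20",
                    "n_q30",
                    "n_pass_quality",
                ):
                    setattr(qc, attr, getattr(qc, attr) + getattr(part_qc, attr))
        counts.write_tsv(outdir / "counts.tsv", outdir / "rejections.tsv")
        write_qc_json(qc, outdir / "qc.json")
    except Exception as exc:
        raise StageFailure("process", exc) from exc
    manifest["stages"]["process"] = {
        "n_pairs": counts.n_pairs,
        "n_accepted": counts.n_accepted,
        "rejections": dict(counts.rejections),
        "q20_pct": qc.q20_pct,
        "q30_pct": qc.q30_pct,
        "pass_pct": qc.pass_pct,
        "seconds": round(time.perf_counter() - stage_t, 3),
    }
    logger.info(
        "[process] %d pairs, %d accepted", counts.n_pairs, counts.n_accepted
    )

    # --- enrich ---------------------------------------------------------
    stage_t = time.perf_counter()
    try:
        enr = config.enrich
        table = CountTable.from_tsv(outdir / "counts.tsv")
        ef_table = peptide_ef(table, pseudocount=float(enr["pseudocount"]))
        ranked = rank_top(
            ef_table,
            min_count_after=int(enr["min_count_after"]),
            top_n=int(enr["top_n"]),
        )
        full_rank = rank_top(
            ef_table, min_count_after=int(enr["min_count_after"]), top_n=None
        )
        out = ef_table.copy()
        out["rank"] = full_rank["rank"].reindex(out.index)
        out = out.sort_index()
        out.to_csv(outdir / "enrichment.tsv", sep="\t")
        ranked.to_csv(outdir / "top_peptides.tsv", sep="\t")
        pos = position_aa_ef(table, design)
        pos.ef.to_csv(outdir / "position_ef.csv")
        pos.counts_before.to_csv(outdir / "position_counts_before.csv")
        pos.counts_after.to_csv(outdir / "position_counts_after.csv")
        consensus, ties = heatmap_consensus(pos.ef)
        write_consensus_json(design, consensus, ties, outdir / "consensus.json")
        if len(ranked):
            logo = logo_matrix(ranked.index)
            logo.to_csv(outdir / "logo_top.csv")
    except Exception as exc:
        raise StageFailure("enrich", exc) from exc
    manifest["stages"]["enrich"] = {
        "n_peptides": int(len(ef_table)),
        "n_ranked": int(len(full_rank)),
        "seconds": round(time.perf_counter() - stage_t, 3),
    }
    logger.info("[enrich] %d peptides, %d ranked", len(ef_table), len(full_rank))

    # --- analyze --------------------------------------------------------
    if config.analyze["enabled"]:
        stage_t = time.perf_counter()
        try:
            ana = config.analyze
            data = ef_table[
                ef_table["ef"].notna()
                & (ef_table["ef"] > 0)
                & (ef_table["c_before"] >= int(ana["min_count_before"]))
            ].sort_index()
            rf_seed = derive_seed(config.seed, "analyze")
            if ana["max_peptides"] and len(data) > int(ana["max_peptides"]):
                # seeded random subsample: preserves the EF population
                # structure (a top-by-count cut would condition on count
                # noise and bias the importances)
                rng = np.random.default_rng(rf_seed)
                keep = np.sort(
                    rng.choice(len(data), int(ana["max_peptides"]), replace=False)
                )
                data = data.iloc[keep]
            y = data["ef"]
            if ana["log_response"]:
                y = np.log(y)
            X = one_hot_encode(data.index, design)
            rf_params = dict(ana["rf_params"] or {})
            if int(ana["hypertune_iters"]) > 0:
                rf_params, _ = hypertune(
                    X,
                    y,
                    n_iter=int(ana["hypertune_iters"]),
                    k=int(ana["folds"]),
                    n_estimators=int(ana["n_estimators"]),
                    seed=rf_seed,
                )
            fit = fit_rf_cv(
                X,
                y,
                k=int(ana["folds"]),
                n_estimators=int(ana["n_estimators"]),
                seed=rf_seed,
                **rf_params,
            )
            report = permutation_importance_cv(
                fit, X, y, n_repeats=int(ana["repeats"]), seed=rf_seed
            )
            report.to_csv(outdir / "importance.tsv", sep="\t", index=False)

            hydro = hydrophobic_count_analysis(
                data.index, data["ef"], design, alpha=float(ana["alpha"])
            )
            hydro.groups.to_csv(
                outdir / "hydrophobicity_groups.tsv", sep="\t", index=False
            )
            hydro.tests.to_csv(
                outdir / "hydrophobicity_tests.tsv", sep="\t", index=False
            )
            pol = polarity_by_position(
                data.index, data["ef"], design, alpha=float(ana["alpha"])
            )
            pol_groups = pd.concat(
                [g.groups.assign(position=f"{rel:+d}") for rel, g in pol.items()]
            )
            pol_tests = pd.concat(
                [g.tests.assign(position=f"{rel:+d}") for rel, g in pol.items()]
            )
            pol_groups.to_csv(
                outdir / "polarity_groups.tsv", sep="\t", index=False
            )
            pol_tests.to_csv(outdir / "polarity_tests.tsv", sep="\t", index=False)
        except Exception as exc:
            raise StageFailure("analyze", exc) from exc
        manifest["stages"]["analyze"] = {
            "n_rows": int(len(data)),
            "cv_mse": fit.mean_mse,
            "top_feature": report.iloc[0]["feature"] if len(report) else None,
            "seconds": round(time.perf_counter() - stage_t, 3),
        }
        logger.info("[analyze] %d rows, CV MSE %.4g", len(data), fit.mean_mse)

    manifest["total_seconds"] = round(time.perf_counter() - t_all, 3)
    _atomic_write_json(manifest, outdir / "manifest.json")
    return manifest
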