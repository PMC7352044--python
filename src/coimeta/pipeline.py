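"""End-to-end driver: simulate/load -> coincidence -> mega -> screen -> overlap.

A single YAML (or dict) configuration names each stage's inputs — either paths
to existing TSVs or synthetic specs — and every stage writes plain TSVs into
the run directory so any stage can be re-run standalone. A summary JSON, the
config echo, and a log with package versions and seeds are written for
provenance. Stage failures abort with the stage name and the original cause.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .coincidence import coincidence_report, write_report
from .errors import DataError, PipelineStageError
from .io import read_cohort, read_study_manifest, write_cohort, write_study_collection
from .meta import run_mega
from .overlap import fisher_overlap, read_gene_sets
from .screening import SignificanceCriteria, apply_criteria
from .synthetic import (
    CohortSpec,
    ExpressionStudySpec,
    simulate_cohort,
    simulate_expression_studies,
    simulate_gene_sets,
)

__all__ = ["run_pipeline", "load_config"]

logger = logging.getLogger("coimeta")


def load_config(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise DataError(f"config file not found: {path}")
    with open(path) as fh:
        return yaml.safe_load(fh)


def _setup_logging(out_dir: Path) -> None:
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    for handler in (
        logging.StreamHandler(sys.stderr),
        logging.FileHandler(out_dir / "pipeline.log", mode="w"),
    ):
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(handler)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                logger.info("stage %s: start", name)
                out = fn(*args, **kwargs)
                logger.info("stage %s: done", name)
                return out
            except PipelineStageError:
                raise
            except Exception as exc:  # noqa: BLE001 — re-raise with stage context
                raise PipelineStageError(name, exc) from exc

        return wrapped

    return deco


@_stage("cohort")
def _get_cohort(cfg: dict, out_dir: Path, seed: int) -> pd.DataFrame:
    if "path" in cfg:
        p = Path(cfg["path"])
        if not p.exists():
            raise DataError(f"cohort file not found: {p}")
        cohort = read_cohort(p)
    else:
        spec = CohortSpec(**{**cfg.get("synthetic", {}), "seed": cfg.get("seed", seed)})
        cohort = simulate_cohort(spec)
    write_cohort(cohort, out_dir / "cohort.tsv")
    return cohort


@_stage("coincidence")
def _run_coincidence(cohort: pd.DataFrame, out_dir: Path):
    report = coincidence_report(cohort)
    write_report(report, out_dir)
    return report


@_stage("studies")
def _get_studies(cfg: dict, out_dir: Path, seed: int):
    if "manifest" in cfg:
        return read_study_manifest(cfg["manifest"])
    syn = dict(cfg.get("synthetic", {}))
    genes = tuple(syn.pop("genes"))
    planted = syn.pop("planted_lfc", {})
    specs = []
    for i, s in enumerate(syn.pop("studies")):
        specs.append(
            ExpressionStudySpec(
                genes=genes,
                planted_lfc=planted,
                seed=seed * 10_000 + i,
                **{**syn, **s},
            )
        )
    studies = simulate_expression_studies(specs)
    write_study_collection(studies, out_dir / "studies", truth=planted)
    return studies


@_stage("mega")
def _run_mega(studies, genes, het_alpha: float, out_dir: Path):
    meta, effects = run_mega(studies, genes, het_alpha=het_alpha)
    meta.to_csv(out_dir / "meta_results.tsv", sep="\t", index=False)
    effects.to_csv(out_dir / "study_effects.tsv", sep="\t", index=False)
    return meta, effects


@_stage("screen")
def _run_screen(meta: pd.DataFrame, criteria: SignificanceCriteria, out_dir: Path):
    up, down, rejected = apply_criteria(meta, criteria)
    up.to_csv(out_dir / "significant_up.tsv", sep="\t", index=False)
    down.to_csv(out_dir / "significant_down.tsv", sep="\t", index=False)
    rejected.to_csv(out_dir / "rejected.tsv", sep="\t", index=False)
    return up, down, rejected


@_stage("overlap")
def _run_overlap(cfg: dict, out_dir: Path, seed: int):
    if "set_a" in cfg:
        set_a = read_gene_sets(cfg["set_a"])
        set_b = read_gene_sets(cfg["set_b"])
        n_background = int(cfg["background_size"])
    else:
        syn = cfg["synthetic"]
        set_a, set_b, background = simulate_gene_sets(
            n_background=syn["n_background"],
            n_setA=syn["n_setA"],
            n_setB=syn["n_setB"],
            n_overlap=syn["n_overlap"],
            seed=syn.get("seed", seed),
        )
        n_background = len(background)
    result = fisher_overlap(set_a, set_b, n_background, cfg.get("alternative", "greater"))
    pd.DataFrame([result.__dict__]).to_csv(out_dir / "overlap.tsv", sep="\t", index=False)
    return result


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> Path:
    """Execute the configured stages in order; returns the run directory."""
    if not isinstance(config, dict):
        config = load_config(config)
    out_dir = Path(out_dir or config.get("output_dir", "coimeta_run"))
    out_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(out_dir)
    seed = int(config.get("seed", 0))
    logger.info("coimeta %s, master seed %d", __version__, seed)

    with open(out_dir / "config_echo.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)

    summary: dict = {"seed": seed, "version": __version__}

    if "cohort" in config:
        cohort = _get_cohort(config["cohort"], out_dir, seed)
        report = _run_coincidence(cohort, out_dir)
        r = report.coincidence.rounded()
        summary["coincidence"] = {
            "p_ec_given_uf_pct": r.p_ec_given_uf,
            "p_ec_given_not_uf_pct": r.p_ec_given_not_uf,
            "ratio_change_pct": r.ratio_change_pct,
            "overall_incidence_pct": r.overall_incidence_pct,
        }

    if "studies" in config:
        studies = _get_studies(config["studies"], out_dir, seed)
        genes = sorted({g for s in studies for g in s.matrix.index})
        het_alpha = float(config.get("het_alpha", 0.10))
        meta, _ = _run_mega(studies, genes, het_alpha, out_dir)
        criteria = SignificanceCriteria(**config.get("criteria", {}))
        up, down, rejected = _run_screen(meta, criteria, out_dir)
        summary["mega"] = {
            "n_genes": len(meta),
            "significant_up": sorted(up["gene"]),
            "significant_down": sorted(down["gene"]),
            "n_rejected": len(rejected),
        }

    if "overlap" in config:
        result = _run_overlap(config["overlap"], out_dir, seed)
        summary["overlap"] = {
            "n_overlap": result.n_overlap,
            "p_value": result.p_value,
            "odds_ratio": result.odds_ratio,
        }

    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("run complete: %s", out_dir)
    return out_dir
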