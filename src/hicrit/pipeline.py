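"""One-command orchestration: simulate -> panel -> regress -> HC -> bootstrap -> summarize.

A single YAML config drives the whole run; every stage writes its artifact
into the output directory and the run closes with a manifest recording the
config echo, seeds, fit dimensions, HC decision and bootstrap accounting.
All randomness funnels through one master seed (stage seeds are derived from
it by fixed offsets), so re-running the same config reproduces identical
outputs.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__
from .bootstrap import bootstrap_tally, rank_edges
from .cohort import (
    EffectSpec,
    make_node_annotation,
    plant_random_edges,
    read_annotation,
    read_subjects,
    simulate_connectomes,
    simulate_subjects,
    write_annotation,
    write_subjects,
)
from .connectome import ConnectivityPanel, edge_count
from .hc import hc_curve, hc_decide, hc_select
from .regression import build_design_matrix, fit_edge_regressions
from .summaries import classify_edges, export_summary, signed_degree_centrality

logger = logging.getLogger("hicrit.pipeline")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CohortBlock(_Strict):
    n: int = 77
    path: Optional[str] = None

    @model_validator(mode="after")
    def _one_source(self):
        return self


class AnnotationBlock(_Strict):
    path: Optional[str] = None
    networks: Optional[dict[str, int]] = None


class EffectsBlock(_Strict):
    n_planted: int = 100
    beta_per_sd: float = 0.1
    frac_negative: float = 0.5  # about half the study's associations were negative
    baseline_z: float = 0.25
    noise_sd: float = 0.3
    edge_ids: Optional[list[int]] = None  # explicit planted set overrides n_planted


class RegressionBlock(_Strict):
    madrs_threshold: int = 14


class HCBlock(_Strict):
    threshold: float = 2.0
    alpha0: Optional[float] = None
    plus: bool = False


class BootstrapBlock(_Strict):
    B: int = 100
    threshold: float = 2.0


class RunConfig(_Strict):
    """Validated pipeline configuration (YAML-friendly)."""

    seed: int = 0
    out_dir: str = "hicrit_run"
    cohort: CohortBlock = Field(default_factory=CohortBlock)
    annotation: AnnotationBlock = Field(default_factory=AnnotationBlock)
    panel_path: Optional[str] = None  # precomputed Fisher-Z panel CSV
    effects: EffectsBlock = Field(default_factory=EffectsBlock)
    regression: RegressionBlock = Field(default_factory=RegressionBlock)
    hc: HCBlock = Field(default_factory=HCBlock)
    bootstrap: BootstrapBlock = Field(default_factory=BootstrapBlock)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)


def _stage(name: str) -> None:
    logger.info("[%s] start", name)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the run manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": json.loads(config.model_dump_json()),
        "version": __version__,
        "stages": [],
    }

    def done(name: str, **info) -> None:
        manifest["stages"].append(name)
        manifest.update(info)
        logger.info("[%s] done %s", name, info or "")

    try:
        _stage("cohort")
        if config.cohort.path:
            subjects = read_subjects(config.cohort.path)
        else:
            subjects = simulate_subjects(config.cohort.n, seed=config.seed)
        write_subjects(subjects, out / "subjects.csv")
        done("cohort", n=len(subjects))

        _stage("annotation")
        if config.annotation.path:
            annotation = read_annotation(config.annotation.path)
        else:
            ann_cfg = (
                {"networks": config.annotation.networks}
                if config.annotation.networks
                else None
            )
            annotation = make_node_annotation(ann_cfg, seed=config.seed)
        write_annotation(annotation, out / "nodes.csv")
        n_edges = edge_count(len(annotation))
        done("annotation", m=len(annotation), n_edges=n_edges)

        _stage("panel")
        if config.panel_path:
            panel = ConnectivityPanel.from_csv(config.panel_path)
            planted = []
        else:
            eff = config.effects
            if eff.edge_ids is not None:
                spec = EffectSpec(
                    planted={int(e): eff.beta_per_sd for e in eff.edge_ids},
                    baseline_z=eff.baseline_z,
                    noise_sd=eff.noise_sd,
                )
            else:
                spec = plant_random_edges(
                    n_edges, eff.n_planted, eff.beta_per_sd, seed=config.seed + 1,
                    frac_negative=eff.frac_negative,
                    baseline_z=eff.baseline_z, noise_sd=eff.noise_sd,
                )
            planted = sorted(spec.planted)
            panel = simulate_connectomes(subjects, annotation, spec, seed=config.seed + 2)
        panel.to_csv(out / "panel.csv")
        panel.edge_index.to_csv(out / "edge_index.csv")
        with open(out / "planted_edges.json", "w") as fh:
            json.dump(planted, fh)
        done("panel", panel_shape=list(panel.values.shape))

        _stage("regress")
        design = build_design_matrix(
            subjects, madrs_threshold=config.regression.madrs_threshold
        )
        results = fit_edge_regressions(panel, design)
        results.to_csv(out / "edge_results.csv")
        done("regress", k=design.k, df=design.df_resid)

        _stage("hc")
        curve = hc_curve(results.p, alpha0=config.hc.alpha0, plus=config.hc.plus)
        decision = hc_decide(curve, config.hc.threshold)
        selected = hc_select(curve, results)
        curve.to_csv(out / "hc_curve.csv")
        decision.to_json(out / "decision.json")
        selected.to_csv(out / "selected.csv")
        done("hc", hc_max=decision.hc_max, i_star=decision.i_star, reject=decision.reject)

        _stage("bootstrap")
        tally = bootstrap_tally(
            subjects,
            panel,
            B=config.bootstrap.B,
            threshold=config.bootstrap.threshold,
            seed=config.seed + 3,
            madrs_threshold=config.regression.madrs_threshold,
            hc_kwargs={"alpha0": config.hc.alpha0, "plus": config.hc.plus},
        )
        tally.to_csv(out / "tally.csv")
        tally.to_json(out / "bootstrap_manifest.json")
        rank_edges(tally, results).to_csv(out / "edge_ranking.csv", index=False)
        done("bootstrap", B=tally.B, B_informative=tally.B_informative)

        _stage("summarize")
        counts = classify_edges(selected, annotation)
        centrality = signed_degree_centrality(selected, annotation, level="region_group")
        export_summary(selected, counts, centrality, annotation, out, decision=decision)
        done("summarize", n_selected=len(selected))
    except Exception as err:
        stage = manifest["stages"][-1] if manifest["stages"] else "config"
        raise RuntimeError(
            f"pipeline failed after stage {stage!r}: {err}; "
            f"completed artifacts are under {out}"
        ) from err

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
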