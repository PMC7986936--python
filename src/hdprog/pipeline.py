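"""End-to-end pipeline: generate or read a cohort, invert subjects, run the
group model, compare and reduce models, and write summary tables.

Every run is driven by a structured YAML config and a single seed; all
randomness flows from that seed through named substreams.  Outputs are tidy
TSV tables plus a JSON manifest recording the config snapshot, seed, module
versions, per-stage timings and a checksum inventory of every file written.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import read_cohort, write_cohort
from .models import StateModelSpec
from .peb import build_design_matrix, fit_peb
from .regions import region_table
from .selection import bma_average, compare_connectivity_models, select_state_model
from .synthetic import CohortConfig, generate_cohort
from .validation import (
    behavior_fit_metrics,
    decade_loss_summary,
    loo_predict,
    variance_explained_over_time,
)
from .vl import PriorSpec, fit_subject

logger = logging.getLogger(__name__)

_CONFIG_KEYS = {"seed", "cohort", "model", "stages", "output_dir",
                "subjects_path", "visits_path"}


@dataclass
class PipelineConfig:
    seed: int = 0
    cohort: dict = field(default_factory=dict)
    model: dict = field(default_factory=lambda: {"form": "dynamic"})
    stages: dict = field(default_factory=lambda: {
        "model_comparison": False, "connectivity": False,
        "bma": True, "summaries": True, "loo": False})
    output_dir: str = "results/run"
    subjects_path: str | None = None  # read an existing cohort instead
    visits_path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class RunManifest:
    config: dict
    seed: int
    versions: dict
    timings: dict
    outputs: dict  # path -> sha256

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"config": self.config, "seed": self.seed,
             "versions": self.versions, "timings": self.timings,
             "outputs": self.outputs}, indent=2, default=str))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig | str | Path,
                 seed: int | None = None) -> RunManifest:
    """Execute the configured stages, writing all artifacts to output_dir."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    if seed is not None:
        config.seed = int(seed)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    written: list[Path] = []

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s started", name)

            def __exit__(self, *exc):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                logger.info("stage %s finished in %.2fs", name, timings[name])
        return _T()

    # --- cohort ------------------------------------------------------------
    with stage("cohort"):
        if config.subjects_path and config.visits_path:
            subjects, series = read_cohort(config.subjects_path,
                                           config.visits_path)
        else:
            cc = CohortConfig(**{**config.cohort, "seed": config.seed})
            subjects, series = generate_cohort(cc)
        write_cohort(subjects, series, out / "subjects.tsv", out / "visits.tsv")
        written += [out / "subjects.tsv", out / "visits.tsv"]
        pd.DataFrame(region_table()).to_csv(out / "regions.tsv", sep="\t",
                                            index=False)
        written.append(out / "regions.tsv")

    # --- subject-level inversion ------------------------------------------
    spec = StateModelSpec(form=config.model.get("form", "dynamic"))
    priors = PriorSpec.default(spec)
    with stage("fit"):
        posteriors = [fit_subject(ts, spec, priors) for ts in series]
        rows = []
        for ts, post in zip(series, posteriors):
            sds = post.sd()
            for j, name in enumerate(spec.param_names):
                rows.append({"subject": ts.subject_id, "parameter": name,
                             "mean": post.mean[j], "sd": sds[j],
                             "free_energy": post.free_energy,
                             "converged": post.converged})
        pd.DataFrame(rows).to_csv(out / "posteriors.tsv", sep="\t", index=False)
        written.append(out / "posteriors.tsv")

    # --- group level -------------------------------------------------------
    with stage("peb"):
        X = build_design_matrix(subjects)
        peb = fit_peb(posteriors, X, priors, param_names=spec.param_names)

    if config.stages.get("bma", True):
        with stage("bma"):
            bma = bma_average(peb)
            rows = []
            for a, pname in enumerate(bma.param_names):
                for j, cname in enumerate(bma.column_labels):
                    rows.append({
                        "parameter": pname, "covariate": cname,
                        "estimate": bma.estimates[a, j], "sd": bma.sds[a, j],
                        "posterior_prob": bma.posterior_probs[a, j],
                        "surviving": bool(bma.surviving[a, j])})
            pd.DataFrame(rows).to_csv(out / "peb_effects.tsv", sep="\t",
                                      index=False)
            written.append(out / "peb_effects.tsv")

    if config.stages.get("model_comparison", False):
        with stage("model_comparison"):
            cmp = select_state_model(subjects, series, X=X)
            pd.DataFrame({"model": cmp.model_ids, "F": cmp.free_energies,
                          "probability": cmp.posterior_probs}).to_csv(
                out / "model_comparison.tsv", sep="\t", index=False)
            written.append(out / "model_comparison.tsv")

    if config.stages.get("connectivity", False):
        with stage("connectivity"):
            cmp = compare_connectivity_models(subjects, series)
            pd.DataFrame({"model": cmp.model_ids, "F": cmp.free_energies,
                          "probability": cmp.posterior_probs}).to_csv(
                out / "connectivity_comparison.tsv", sep="\t", index=False)
            written.append(out / "connectivity_comparison.tsv")

    if config.stages.get("summaries", True):
        with stage("summaries"):
            dls = decade_loss_summary(subjects, series)
            dls.to_csv(out / "decade_loss.tsv", sep="\t")
            written.append(out / "decade_loss.tsv")
            if spec.form == "dynamic":
                r2 = variance_explained_over_time(subjects, posteriors, spec)
                r2.to_csv(out / "r2_over_time.tsv", sep="\t")
                written.append(out / "r2_over_time.tsv")
            if any(ts.behavior is not None for ts in series):
                bf = behavior_fit_metrics(subjects, series, posteriors, spec)
                pd.DataFrame({
                    "channel": list(bf.r2),
                    "r2": [bf.r2[c] for c in bf.r2],
                    "decade_change": [bf.decade_change[c] for c in bf.r2],
                }).to_csv(out / "behavior_metrics.tsv", sep="\t", index=False)
                written.append(out / "behavior_metrics.tsv")

    if config.stages.get("loo", False):
        with stage("loo"):
            loo = loo_predict(subjects, series, "group",
                              spec=spec, priors=priors, posteriors=posteriors)
            pd.DataFrame({"subject": loo.subject_ids,
                          "true": loo.true_values,
                          "predicted": loo.predicted,
                          "p_hd": loo.uncertainty}).to_csv(
                out / "loo_group.tsv", sep="\t", index=False)
            written.append(out / "loo_group.tsv")
            (out / "loo_summary.json").write_text(json.dumps(
                {"accuracy": loo.accuracy, "r": loo.r}))
            written.append(out / "loo_summary.json")

    manifest = RunManifest(
        config=asdict(config), seed=config.seed,
        versions={"hdprog": __version__, "numpy": np.__version__,
                  "pandas": pd.__version__},
        timings=timings,
        outputs={str(p.relative_to(out)): _sha256(p) for p in written})
    manifest.write(out / "manifest.json")
    return manifest
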