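"""One-command pipeline: simulate/load -> extract -> reject -> average ->
select conditions -> fit CRFs -> ratio indices -> group statistics.

Every stage writes its intermediate table as CSV into the output
directory, and a manifest records the configuration hash, seed, row counts
and any warnings, so that a rerun with the same configuration and seed
reproduces every output bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import __version__
from .crf import SupraBaselineSet, fit_crf, select_supra_baseline
from .io import read_recordings
from .paradigms import ParadigmSpec, get_paradigm
from .ratio_stats import (mixed_anova, oneway_anova_contrasts, ratio_index,
                          regress_ratio_on_trait, ttest_ind)
from .spectral import (coherent_average_table, group_scalar_means,
                       reject_artifacts, trial_harmonics_table)
from .synthetic import (CohortConfig, GroundTruth, adult_cohort_config,
                        child_cohort_config, fly_cohort_config,
                        iter_subject_recordings)

__all__ = ["PipelineConfig", "RunManifest", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


class PipelineConfig(BaseModel):
    """End-to-end run configuration.

    With ``input_dir`` unset, a synthetic cohort for the chosen paradigm
    is simulated with ``seed`` (using the per-paradigm preset unless
    ``cohort`` overrides it) and analysed in a single pass.
    """

    model_config = ConfigDict(frozen=True)

    paradigm: str
    analysis_window: tuple[float, float] | None = None
    reject_sd: float = 4.0
    alpha: float = 0.05
    seed: int = 0
    input_dir: str | None = None
    traits_csv: str | None = None
    out_dir: str = "ssvep_out"
    cohort: CohortConfig | None = None
    control_group: str | None = None

    def config_hash(self) -> str:
        payload = self.model_dump_json()
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record written on every run."""

    config_hash: str
    version: str
    seed: int
    counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def write(self, path: Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         sort_keys=True) + "\n")


def _default_cohort(paradigm_name: str, seed: int) -> CohortConfig:
    if paradigm_name == "fly":
        return fly_cohort_config(seed=seed)
    if paradigm_name == "adult":
        return adult_cohort_config(seed=seed)
    if paradigm_name == "child_sweep":
        return child_cohort_config(seed=seed)
    raise KeyError(f"no default cohort for paradigm {paradigm_name!r}")


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - tag and re-raise
                raise PipelineError(name, str(exc)) from exc
        return inner
    return wrap


@_stage("extract")
def _extract(config: PipelineConfig, paradigm: ParadigmSpec) -> pd.DataFrame:
    window = config.analysis_window or paradigm.analysis_window
    if config.input_dir is not None:
        recordings = read_recordings(Path(config.input_dir))
        if paradigm.sweep:
            return trial_harmonics_table(recordings)
        return trial_harmonics_table(recordings, analysis_window=window)
    cohort = config.cohort or _default_cohort(config.paradigm, config.seed)
    if cohort.seed != config.seed:
        cohort = cohort.model_copy(update={"seed": config.seed})
    frames = []
    for _, recs in iter_subject_recordings(cohort, paradigm):
        if paradigm.sweep:
            frames.append(trial_harmonics_table(recs))
        else:
            frames.append(trial_harmonics_table(recs, analysis_window=window))
    return pd.concat(frames, ignore_index=True)


def _stats_battery(config: PipelineConfig, responses: pd.DataFrame,
                   indices: pd.DataFrame, traits: pd.DataFrame | None):
    groups = list(pd.unique(responses["group"]))
    top = responses["contrast"].max()
    at_top = responses[responses["contrast"] == top]
    results = []

    def add(label, res):
        results.append((label, res))

    if len(groups) == 2:
        for key, res in mixed_anova(at_top).items():
            add(f"mixed_anova_{key}", res)
        a = indices.loc[indices["group"] == groups[0], "value"]
        b = indices.loc[indices["group"] == groups[1], "value"]
        add("ratio_ttest", ttest_ind(a, b))
    elif len(groups) >= 3:
        control = config.control_group or groups[0]
        for harmonic in (1, 2):
            sub = at_top[at_top["harmonic"] == harmonic].rename(
                columns={"amplitude": "value"})
            for key, res in oneway_anova_contrasts(sub, control).items():
                add(f"amp_{harmonic}f_{key}", res)
        for key, res in oneway_anova_contrasts(indices, control).items():
            add(f"ratio_{key}", res)
    if traits is not None:
        merged = indices.merge(traits, on="subject_id", how="inner")
        if len(merged) >= 3:
            add("trait_regression",
                regress_ratio_on_trait(merged["score"], merged["value"]))
    return results


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full analysis chain; returns the written manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        paradigm = get_paradigm(config.paradigm)
    except KeyError as exc:
        raise PipelineError("config", str(exc)) from exc
    if config.reject_sd <= 0:
        raise PipelineError("config", "rejection threshold must be positive")

    manifest = RunManifest(config_hash=config.config_hash(), version=__version__,
                           seed=config.seed)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        trials = _extract(config, paradigm)
        trials_out = trials.drop(columns="coef")
        trials_out.to_csv(out / "trial_harmonics.csv", index=False)

        kept, rejected = _stage("reject")(reject_artifacts)(
            trials, threshold_sd=config.reject_sd)
        rejected.drop(columns="coef").to_csv(out / "rejected_repetitions.csv",
                                             index=False)

        responses = _stage("average")(coherent_average_table)(kept)
        responses.to_csv(out / "amplitudes.csv", index=False)
        group_means = group_scalar_means(responses)
        group_means.to_csv(out / "group_means.csv", index=False)

        supra = _stage("select_conditions")(select_supra_baseline)(
            responses, harmonic=1, alpha=config.alpha)
        (out / "conditions.json").write_text(
            json.dumps(supra.to_dict(), indent=2) + "\n")

        fits = []
        for (group, harmonic), sub in group_means.groupby(["group", "harmonic"]):
            crf = _stage("fit_crf")(fit_crf)(sub["contrast"], sub["amplitude"])
            fits.append({"group": group, "harmonic": harmonic,
                         **dataclasses.asdict(crf)})
        pd.DataFrame(fits).to_csv(out / "crf_fits.csv", index=False)

        if len(supra.selected_contrasts) == 0:
            raise PipelineError("ratio_index",
                                "no supra-baseline conditions selected")
        indices = _stage("ratio_index")(ratio_index)(responses, supra)
        indices.to_csv(out / "ratios.csv", index=False)

        traits = None
        if config.traits_csv is not None:
            traits = pd.read_csv(config.traits_csv)
            if not {"subject_id", "score"}.issubset(traits.columns):
                raise PipelineError("stats",
                                    "traits CSV needs subject_id and score columns")
        stats = _stage("stats")(_stats_battery)(config, responses, indices, traits)

    stats_rows = []
    report_lines = []
    for label, res in stats:
        dof = "x".join(f"{d:g}" for d in res.dof)
        stats_rows.append({
            "label": label, "test": res.test, "effect": res.effect,
            "statistic": res.statistic, "dof": dof, "p_value": res.p_value,
            "effect_direction": res.effect_direction,
            **{f"extra_{k}": v for k, v in res.extra.items()},
        })
        report_lines.append(
            f"{label:32s} {res.test:18s} stat={res.statistic:8.3f} "
            f"dof=({dof}) p={res.p_value:.4g}")
    pd.DataFrame(stats_rows).to_csv(out / "stats.csv", index=False)
    (out / "report.txt").write_text("\n".join(report_lines) + "\n")

    manifest.counts = {
        "n_trial_rows": int(len(trials)),
        "n_subjects": int(responses["subject_id"].nunique()),
        "n_contrasts": int(responses["contrast"].nunique()),
        "n_harmonics": int(responses["harmonic"].nunique()),
        "n_repetitions_rejected": int(len(rejected)),
        "n_supra_conditions": int(len(supra.selected_contrasts)),
        "n_stat_tests": len(stats_rows),
    }
    manifest.warnings = sorted({str(w.message) for w in caught})
    manifest.write(out / "manifest.json")
    return manifest
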