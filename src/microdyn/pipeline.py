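"""End-to-end orchestration: simulate/load -> condition -> cluster -> group maps
-> back-fit -> temporal metrics -> transition and spectral summaries.

The pipeline mirrors the standard group microstate workflow: subject-level
TAAHC at GFP peaks with an automatic choice of k, a cohort-level k fixed at
the median of the subject optima, per-group permutation-averaged maps, and
back-fitting of the group maps to every subject's epochs.  All randomness
derives from one master seed; per-subject seeds are spawned deterministically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .cluster import group_mean_maps
from .estimators import MicrostateSegmenter
from .io import FLOAT_FMT, write_model
from .preprocessing import average_reference, bandpass_filter, epoch_and_select
from .segment import Segmentation, temporal_metrics
from .spectral import band_power, dominant_frequency
from .synthetic import CohortSubject, make_topographies, simulate_cohort
from .transitions import transition_matrix, transition_randomness_test

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


class PipelineConfig(BaseModel):
    """Validated configuration of one pipeline run (the resolved config and
    seed are written next to the outputs for provenance)."""

    # cohort simulation (used when no recordings are supplied)
    n_channels: int = Field(64, ge=8)
    k_true: int = Field(5, ge=1)
    n_per_group: list[int] = [10, 10]
    group_dwell_ms: list[float] = [64.7, 77.0]
    group_names: list[str] | None = None
    fs: float = Field(256.0, gt=0)
    duration_s: float = Field(70.0, gt=0)
    carrier_hz: float = 10.0
    snr: float = 5.0
    template_jitter: float = 0.0
    # conditioning
    band: tuple[float, float] = (2.0, 20.0)
    filter_order: int = 2
    epoch_s: float = 2.0
    n_epochs: int = 30
    reject_threshold_uv: float | None = 500.0
    # clustering / fitting
    k_mode: str = "auto"  # "auto" | "fixed"
    k_fixed: int = 5
    k_range: tuple[int, int] = (1, 12)
    fit_mode: str = "peaks_interpolated"
    polarity_invariant: bool = True
    # statistics
    n_shuffles: int = 1000
    run_spectral: bool = True
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if len(self.n_per_group) != len(self.group_dwell_ms):
            raise ValueError("n_per_group and group_dwell_ms lengths differ")
        if self.k_mode not in ("auto", "fixed"):
            raise ValueError("k_mode must be 'auto' or 'fixed'")
        if self.fit_mode not in ("peaks_interpolated", "all_samples"):
            raise ValueError("unknown fit_mode")
        if not self.k_range[0] <= self.k_range[1]:
            raise ValueError("invalid k_range")
        return self


@dataclass
class PipelineResult:
    metrics: pd.DataFrame  # one row per subject
    group_maps: dict[str, np.ndarray]
    segmentations: dict[str, Segmentation]
    transition_reports: dict[str, dict]
    cohort_k: int
    config: PipelineConfig


def _lower_median(values: list[int]) -> int:
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def run_pipeline(
    config: PipelineConfig,
    cohort: list[CohortSubject] | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis; optionally write all outputs under ``out_dir``."""
    if cohort is None:
        templates = make_topographies(config.n_channels, config.k_true,
                                      seed=config.seed)
        cohort = simulate_cohort(
            config.n_per_group, config.group_dwell_ms, templates,
            fs=config.fs, duration_s=config.duration_s,
            carrier_hz=config.carrier_hz, snr=config.snr,
            template_jitter=config.template_jitter,
            group_names=config.group_names, seed=config.seed,
        )

    # stage 1: conditioning + subject-level models
    epoch_sets, subj_models, chosen_k = {}, {}, {}
    for sub in cohort:
        try:
            rec = bandpass_filter(sub.recording, *config.band,
                                  order=config.filter_order)
            rec = average_reference(rec)
            eps = epoch_and_select(rec, config.epoch_s, config.n_epochs,
                                   config.reject_threshold_uv)
            epoch_sets[sub.subject_id] = eps
            if config.k_mode == "auto":
                m = MicrostateSegmenter(
                    n_states="auto", k_range=config.k_range,
                    polarity_invariant=config.polarity_invariant,
                    fit_mode=config.fit_mode,
                ).fit(eps)
                chosen_k[sub.subject_id] = m.n_states_
        except Exception as err:
            raise RuntimeError(
                f"stage 'subject_model' failed for {sub.subject_id}: {err}"
            ) from err

    cohort_k = (_lower_median(list(chosen_k.values()))
                if config.k_mode == "auto" else config.k_fixed)

    # stage 2: re-fit every subject at the cohort-level k
    for sub in cohort:
        m = MicrostateSegmenter(
            n_states=cohort_k, polarity_invariant=config.polarity_invariant,
            fit_mode=config.fit_mode,
        ).fit(epoch_sets[sub.subject_id])
        subj_models[sub.subject_id] = m

    # stage 3: per-group permutation-averaged maps
    groups = sorted({s.group for s in cohort})
    group_maps: dict[str, np.ndarray] = {}
    for g in groups:
        tsets = [subj_models[s.subject_id].templates_ for s in cohort
                 if s.group == g]
        group_maps[g], _ = group_mean_maps(
            tsets, polarity_invariant=config.polarity_invariant
        )

    # stage 4: back-fit group maps, temporal metrics, transitions, spectra
    rows, segmentations, transition_reports = [], {}, {}
    seed_seq = np.random.SeedSequence(config.seed + 1)
    shuffle_seeds = seed_seq.generate_state(len(cohort)) % (2**31 - 1)
    for i, sub in enumerate(cohort):
        m = subj_models[sub.subject_id]
        seg = m.predict(epoch_sets[sub.subject_id],
                        templates=group_maps[sub.group])
        segmentations[sub.subject_id] = seg
        tm = temporal_metrics(seg)
        row: dict = {
            "subject": sub.subject_id,
            "group": sub.group,
            "k_auto": chosen_k.get(sub.subject_id),
            "k_used": cohort_k,
            "gev": m.gev_,
            "mean_duration_ms": tm.mean_duration_ms,
            "total_occurrence_per_s": tm.total_occurrence_per_s,
            "gfp_peaks_per_s": tm.gfp_peaks_per_s,
        }
        for c in range(cohort_k):
            row[f"duration_ms_{c}"] = tm.duration_ms[c]
            row[f"occurrence_per_s_{c}"] = tm.occurrence_per_s[c]
            row[f"coverage_{c}"] = tm.coverage[c]
        if config.run_spectral:
            rec = average_reference(sub.recording)
            row["dominant_hz"] = dominant_frequency(rec, epoch_s=config.epoch_s)
            bp = band_power(rec, relative=True, epoch_s=config.epoch_s)
            for name, v in bp.band_power.items():
                row[f"relpow_{name}"] = v
        rows.append(row)
        tmat = transition_matrix(seg)
        report = transition_randomness_test(
            seg, n_shuffles=config.n_shuffles, seed=int(shuffle_seeds[i])
        )
        report["observed"] = np.nan_to_num(tmat.observed).tolist()
        report["expected"] = tmat.expected.tolist()
        transition_reports[sub.subject_id] = report

    metrics = pd.DataFrame(rows)
    result = PipelineResult(metrics, group_maps, segmentations,
                            transition_reports, cohort_k, config)
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.metrics.to_csv(out_dir / "metrics.csv", index=False,
                          float_format=FLOAT_FMT)
    for g, maps in result.group_maps.items():
        write_model(maps, out_dir / f"group_maps_{g}.csv")
    (out_dir / "transitions.json").write_text(
        json.dumps(result.transition_reports, indent=1)
    )
    (out_dir / "config.json").write_text(json.dumps(
        {"version": __version__, "cohort_k": result.cohort_k,
         **result.config.model_dump()},
        indent=1, default=str,
    ))
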