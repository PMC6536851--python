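"""Back-fitting templates to data and temporal microstate statistics.

In the standard (peak-interpolated) mode every GFP peak is assigned to the
template with the highest |spatial correlation| and the samples between
consecutive peaks inherit the nearer peak's label, with the boundary at the
midpoint; microstates therefore start and end halfway between two GFP peaks.
Runs touching an epoch edge are flagged as potentially truncated and excluded
from the temporal statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .maps import compute_gfp, correlation_matrix
from .recording import EpochSet, unit_gfp

__all__ = [
    "UNASSIGNED",
    "Segmentation",
    "TemporalMetrics",
    "backfit",
    "extract_runs",
    "temporal_metrics",
]

UNASSIGNED = -1


@dataclass
class Segmentation:
    """Per-sample microstate labels for a set of epochs.

    ``labels`` holds class indices 0..k-1 or :data:`UNASSIGNED`; ``truncated``
    marks samples belonging to runs that touch an epoch edge (potentially cut
    short by the epoching).
    """

    labels: np.ndarray  # (n_epochs, samples_per_epoch) int
    truncated: np.ndarray  # same shape, bool
    fs: float
    n_classes: int
    source: str  # "peaks_interpolated" | "all_samples"
    n_peaks: int = 0  # total GFP peaks over all epochs

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.truncated = np.asarray(self.truncated, dtype=bool)
        if self.labels.shape != self.truncated.shape or self.labels.ndim != 2:
            raise ValueError("labels and truncated must be matching 2-D arrays")
        valid = (self.labels == UNASSIGNED) | (
            (self.labels >= 0) & (self.labels < self.n_classes)
        )
        if not np.all(valid):
            raise ValueError("labels must lie in 0..k-1 or UNASSIGNED")
        if self.source not in ("peaks_interpolated", "all_samples"):
            raise ValueError(f"unknown source {self.source!r}")

    @property
    def n_epochs(self) -> int:
        return self.labels.shape[0]

    @property
    def samples_per_epoch(self) -> int:
        return self.labels.shape[1]


@dataclass
class TemporalMetrics:
    """Per-class and mean temporal statistics of one segmentation.

    Durations are mean run lengths in ms over non-truncated runs; occurrence
    counts non-truncated run starts per second of analyzed (assigned,
    non-truncated) time; coverage is each class's share of that time.  A class
    with no runs has NaN duration and zero occurrence/coverage.
    """

    duration_ms: np.ndarray  # (k,)
    mean_duration_ms: float  # pooled over all non-truncated runs
    occurrence_per_s: np.ndarray  # (k,)
    mean_occurrence_per_s: float  # mean over classes
    total_occurrence_per_s: float  # distinct microstates per second
    coverage: np.ndarray  # (k,), sums to 1
    gfp_peaks_per_s: float
    n_classes: int


def _interpolate_peak_labels(
    peaks: np.ndarray, peak_labels: np.ndarray, n_samples: int
) -> np.ndarray:
    """Spread peak labels to all samples; boundaries halfway between peaks."""
    labels = np.empty(n_samples, dtype=int)
    edges = [0]
    for a, b in zip(peaks[:-1], peaks[1:]):
        edges.append((int(a) + int(b) + 1) // 2)
    edges.append(n_samples)
    for i in range(len(peaks)):
        labels[edges[i] : edges[i + 1]] = peak_labels[i]
    return labels


def _flag_edge_runs(labels: np.ndarray) -> np.ndarray:
    """Boolean mask of samples in the first and last run of one epoch."""
    n = labels.size
    trunc = np.zeros(n, dtype=bool)
    if n == 0:
        return trunc
    change = np.flatnonzero(np.diff(labels) != 0)
    first_end = (change[0] + 1) if change.size else n
    last_start = (change[-1] + 1) if change.size else 0
    trunc[:first_end] = True
    trunc[last_start:] = True
    return trunc


def backfit(
    templates: np.ndarray,
    epochs: EpochSet,
    mode: str = "peaks_interpolated",
    polarity_invariant: bool = True,
) -> Segmentation:
    """Label every sample of every epoch with its best-fitting template.

    ``peaks_interpolated`` labels GFP peaks by maximal |spatial correlation|
    and interpolates between them (robust default); ``all_samples`` labels
    every sample independently (robustness variant).  Epochs with fewer than
    two GFP peaks in peak mode are skipped with a warning and left
    unassigned.
    """
    if mode not in ("peaks_interpolated", "all_samples"):
        raise ValueError(f"unknown backfit mode {mode!r}")
    templates = unit_gfp(np.atleast_2d(np.asarray(templates, dtype=float)))
    k = templates.shape[0]
    n_ep, _, spe = epochs.epochs.shape
    labels = np.full((n_ep, spe), UNASSIGNED, dtype=int)
    truncated = np.zeros((n_ep, spe), dtype=bool)
    n_peaks_total = 0
    for e in range(n_ep):
        ep = epochs.epochs[e]
        gfp = compute_gfp(ep)
        n_peaks_total += gfp.n_peaks
        if mode == "peaks_interpolated":
            if gfp.n_peaks < 2:
                warnings.warn(
                    f"epoch {e}: fewer than 2 GFP peaks; epoch skipped",
                    stacklevel=2,
                )
                truncated[e, :] = True
                continue
            peak_maps = ep[:, gfp.peak_indices].T
            c = correlation_matrix(peak_maps, templates)
            if polarity_invariant:
                c = np.abs(c)
            peak_labels = np.argmax(c, axis=1)
            labels[e] = _interpolate_peak_labels(gfp.peak_indices, peak_labels, spe)
        else:
            ok = gfp.values > 0
            if np.any(ok):
                c = correlation_matrix(ep[:, ok].T, templates)
                if polarity_invariant:
                    c = np.abs(c)
                lab = np.full(spe, UNASSIGNED, dtype=int)
                lab[ok] = np.argmax(c, axis=1)
                labels[e] = lab
        truncated[e] = _flag_edge_runs(labels[e])
    return Segmentation(labels, truncated, epochs.fs, k, mode, n_peaks_total)


def extract_runs(seg: Segmentation) -> list[tuple[int, int, int, bool]]:
    """All maximal constant-label runs as (epoch, label, length, truncated).

    Runs never cross epoch boundaries; a run is truncated when any of its
    samples carries the truncation flag.
    """
    out: list[tuple[int, int, int, bool]] = []
    for e in range(seg.n_epochs):
        lab = seg.labels[e]
        change = np.flatnonzero(np.diff(lab) != 0)
        starts = np.concatenate([[0], change + 1])
        ends = np.concatenate([change + 1, [lab.size]])
        for s, t in zip(starts, ends):
            out.append((e, int(lab[s]), int(t - s), bool(seg.truncated[e, s:t].any())))
    return out


def temporal_metrics(seg: Segmentation) -> TemporalMetrics:
    """Duration, occurrence, coverage, and GFP-peak rate from a segmentation.

    Truncated runs are excluded everywhere.  "Analyzed time" is the assigned,
    non-truncated time, which makes duration x occurrence = coverage x 1000
    an exact per-class identity.
    """
    k = seg.n_classes
    ms_per_sample = 1000.0 / seg.fs
    runs = [(lab, length) for _, lab, length, trunc in extract_runs(seg)
            if not trunc and lab != UNASSIGNED]
    if not runs:
        raise ValueError("segmentation has no non-truncated assigned runs")
    run_labels = np.array([r[0] for r in runs])
    run_lengths = np.array([r[1] for r in runs], dtype=float)
    total_samples = float(run_lengths.sum())
    analyzed_s = total_samples / seg.fs

    duration = np.full(k, np.nan)
    occurrence = np.zeros(k)
    coverage = np.zeros(k)
    for c in range(k):
        sel = run_labels == c
        n_runs = int(sel.sum())
        if n_runs == 0:
            warnings.warn(
                f"class {c} has no non-truncated runs; duration undefined",
                stacklevel=2,
            )
            continue
        duration[c] = run_lengths[sel].mean() * ms_per_sample
        occurrence[c] = n_runs / analyzed_s
        coverage[c] = run_lengths[sel].sum() / total_samples
    total_time_s = seg.n_epochs * seg.samples_per_epoch / seg.fs
    return TemporalMetrics(
        duration_ms=duration,
        mean_duration_ms=float(run_lengths.mean() * ms_per_sample),
        occurrence_per_s=occurrence,
        mean_occurrence_per_s=float(occurrence.mean()),
        total_occurrence_per_s=float(len(runs) / analyzed_s),
        coverage=coverage,
        gfp_peaks_per_s=float(seg.n_peaks / total_time_s),
        n_classes=k,
    )
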