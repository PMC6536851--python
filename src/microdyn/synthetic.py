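"""Synthetic EEG and network time courses with planted ground truth.

Every stage of the microstate / dFC pipeline is validated on data from this
module: the generators plant template topographies, label sequences with a
known mean dwell time, group contrasts in dwell time, and state-switching
covariance structure for the dynamic-connectivity stage, and hand the exact
ground truth back to the caller.

Generative model for the EEG
----------------------------
A hidden state sequence switches between K template topographies with
geometric (memoryless) run lengths: at each sample the state switches with
probability ``(1000 / fs) / dwell_mean_ms`` and, on a switch, moves to one of
the other K-1 states uniformly.  Within a run the active template is driven
by a rectified oscillatory envelope ``|sin(2*pi*f*(t - t_run_start))|`` whose
phase restarts at the state onset, so that global field power dips at state
transitions and peaks inside each state -- the regime the microstate model
assumes (topographic transitions occur near field-power minima).  Spatially
white, per-sample average-referenced Gaussian noise is added at a requested
signal-to-noise ratio (RMS of the noiseless signal over RMS of the noise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .recording import Recording, TopographySet, unit_gfp

__all__ = [
    "GroundTruth",
    "CohortSubject",
    "NetworkTimecourseSet",
    "make_topographies",
    "simulate_microstate_eeg",
    "simulate_cohort",
    "simulate_network_timecourses",
]


@dataclass
class GroundTruth:
    """Planted truth for one simulated recording."""

    templates: TopographySet
    label_sequence: np.ndarray  # per-sample class index, values in 0..K-1
    dwell_mean_ms: float
    snr: float
    seed: int | None

    def __post_init__(self) -> None:
        self.label_sequence = np.asarray(self.label_sequence, dtype=int)
        k = self.templates.k
        if self.label_sequence.size and (
            self.label_sequence.min() < 0 or self.label_sequence.max() >= k
        ):
            raise ValueError("label_sequence values must lie in 0..K-1")
        if not self.dwell_mean_ms > 0:
            raise ValueError("dwell_mean_ms must be positive")
        if self.snr < 0:
            raise ValueError("snr must be nonnegative")

    def run_lengths(self) -> np.ndarray:
        """Lengths (in samples) of the maximal constant runs of the sequence."""
        lab = self.label_sequence
        if lab.size == 0:
            return np.empty(0, dtype=int)
        change = np.flatnonzero(np.diff(lab) != 0)
        edges = np.concatenate([[-1], change, [lab.size - 1]])
        return np.diff(edges)


@dataclass
class CohortSubject:
    subject_id: str
    group: str
    recording: Recording
    ground_truth: GroundTruth


@dataclass
class NetworkTimecourseSet:
    """Network time courses (networks x volumes) from resting fMRI."""

    data: np.ndarray
    tr_s: float
    network_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 2:
            raise ValueError("need a 2-D matrix with >= 2 networks")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("network time courses contain non-finite values")
        if not self.tr_s > 0:
            raise ValueError("tr_s must be positive")
        if not self.network_names:
            self.network_names = [f"net{i:02d}" for i in range(self.data.shape[0])]

    @property
    def n_networks(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]


def _sensor_layout(n_channels: int) -> np.ndarray:
    """Deterministic 2-D sensor positions on the unit disc (sunflower spiral)."""
    i = np.arange(n_channels) + 0.5
    r = np.sqrt(i / n_channels)
    theta = i * np.pi * (3.0 - np.sqrt(5.0))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def make_topographies(
    n_channels: int,
    k: int,
    smoothness: float = 0.35,
    seed: int | None = None,
    max_abs_corr: float = 0.5,
    max_retries: int = 100,
) -> TopographySet:
    """Draw ``k`` smooth, mutually dissimilar, average-referenced template maps.

    Maps are Gaussian random fields over a synthetic planar sensor layout with
    squared-exponential spatial covariance (length scale ``smoothness`` in
    layout units), average-referenced and scaled to unit RMS.  Draws are
    rejected until every pair satisfies ``|spatial correlation| < max_abs_corr``.
    """
    if n_channels < 8:
        raise ValueError("need at least 8 channels")
    if not 1 <= k <= n_channels - 1:
        raise ValueError(f"k must be in 1..{n_channels - 1}, got {k}")
    pos = _sensor_layout(n_channels)
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
    cov = np.exp(-d2 / (2.0 * smoothness**2)) + 1e-10 * np.eye(n_channels)
    chol = np.linalg.cholesky(cov)
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        maps = rng.standard_normal((k, n_channels)) @ chol.T
        maps -= maps.mean(axis=1, keepdims=True)
        maps = unit_gfp(maps)
        if k == 1:
            return TopographySet(maps)
        c = np.corrcoef(maps)
        off = np.abs(c[np.triu_indices(k, 1)])
        if np.all(off < max_abs_corr):
            return TopographySet(maps)
    raise RuntimeError(
        f"could not draw {k} maps with pairwise |correlation| < {max_abs_corr} "
        f"in {max_retries} attempts; relax the separation bound or smoothness"
    )


def _sample_labels(
    k: int, n_samples: int, switch_prob: float, rng: np.random.Generator
) -> np.ndarray:
    """Geometric run lengths; uniformly random different next state."""
    labels = np.empty(n_samples, dtype=int)
    t = 0
    state = int(rng.integers(k))
    while t < n_samples:
        run = int(rng.geometric(switch_prob))
        labels[t : t + run] = state
        t += run
        if k > 1:
            nxt = int(rng.integers(k - 1))
            state = nxt if nxt < state else nxt + 1
    return labels


def simulate_microstate_eeg(
    templates: TopographySet,
    dwell_mean_ms: float = 80.0,
    fs: float = 256.0,
    duration_s: float = 60.0,
    carrier_hz: float = 10.0,
    snr: float = 5.0,
    seed: int | None = None,
) -> tuple[Recording, GroundTruth]:
    """Simulate average-referenced EEG switching between template topographies.

    Returns the recording and the planted :class:`GroundTruth` (exact label
    sequence).  ``snr=np.inf`` disables the noise entirely.
    """
    if not fs > 0 or not duration_s > 0:
        raise ValueError("fs and duration_s must be positive")
    if dwell_mean_ms < 2.0 * (1000.0 / fs):
        raise ValueError(
            f"dwell_mean_ms must be at least two samples ({2000.0 / fs:.3f} ms)"
        )
    if snr < 0:
        raise ValueError("snr must be nonnegative")
    rng = np.random.default_rng(seed)
    n = int(round(fs * duration_s))
    k = templates.k
    switch_prob = (1000.0 / fs) / dwell_mean_ms
    labels = _sample_labels(k, n, switch_prob, rng)

    # envelope phase restarts at each run onset -> GFP minima at transitions
    change = np.flatnonzero(np.diff(labels) != 0) + 1
    starts = np.concatenate([[0], change])
    run_start = np.repeat(starts, np.diff(np.concatenate([starts, [n]])))
    t_in_run = (np.arange(n) - run_start) / fs
    envelope = np.abs(np.sin(2.0 * np.pi * carrier_hz * t_in_run))

    tmaps = unit_gfp(templates.maps)
    signal = tmaps[labels].T * envelope[None, :]

    if np.isfinite(snr) and snr > 0:
        noise = rng.standard_normal(signal.shape)
        noise -= noise.mean(axis=0, keepdims=True)  # keep the average reference
        sig_rms = np.sqrt(np.mean(signal**2))
        noise_rms = np.sqrt(np.mean(noise**2))
        data = signal + noise * (sig_rms / (snr * noise_rms))
    elif snr == 0:
        warnings.warn("snr=0 produces pure noise", stacklevel=2)
        noise = rng.standard_normal(signal.shape)
        noise -= noise.mean(axis=0, keepdims=True)
        data = noise
    else:  # snr = inf
        data = signal
    rec = Recording(data, fs, list(templates.channel_labels), reference="average")
    truth = GroundTruth(TopographySet(tmaps, list(templates.channel_labels)),
                        labels, dwell_mean_ms, snr, seed)
    return rec, truth


def simulate_cohort(
    n_per_group: list[int],
    group_dwell_ms: list[float],
    shared_templates: TopographySet,
    fs: float = 256.0,
    duration_s: float = 60.0,
    carrier_hz: float = 10.0,
    snr: float = 5.0,
    template_jitter: float = 0.0,
    group_names: list[str] | None = None,
    seed: int | None = None,
) -> list[CohortSubject]:
    """Simulate a multi-group cohort sharing templates with group-specific dwell.

    ``template_jitter`` adds per-subject Gaussian perturbation (fraction of map
    RMS) to the shared templates before simulation, emulating inter-subject
    topographic variability.  Per-subject seeds are spawned deterministically
    from the master seed.
    """
    if len(n_per_group) == 0:
        raise ValueError("need at least one group")
    if len(n_per_group) != len(group_dwell_ms):
        raise ValueError("n_per_group and group_dwell_ms must have equal length")
    if group_names is None:
        group_names = [f"group{g}" for g in range(len(n_per_group))]
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(int(sum(n_per_group)))
    out: list[CohortSubject] = []
    i = 0
    for g, (n_sub, dwell) in enumerate(zip(n_per_group, group_dwell_ms)):
        if n_sub < 1:
            raise ValueError("each group needs at least one subject")
        for _ in range(n_sub):
            child = children[i]
            sub_seed = int(child.generate_state(1)[0] % (2**31 - 1))
            tmaps = shared_templates.maps
            if template_jitter > 0:
                jrng = np.random.default_rng(sub_seed + 1)
                jit = jrng.standard_normal(tmaps.shape) * template_jitter
                jit -= jit.mean(axis=1, keepdims=True)
                tmaps = unit_gfp(tmaps + jit)
            tset = TopographySet(tmaps, list(shared_templates.channel_labels))
            rec, truth = simulate_microstate_eeg(
                tset, dwell_mean_ms=dwell, fs=fs, duration_s=duration_s,
                carrier_hz=carrier_hz, snr=snr, seed=sub_seed,
            )
            out.append(
                CohortSubject(f"sub-{i:03d}", group_names[g], rec, truth)
            )
            i += 1
    return out


def simulate_network_timecourses(
    n_volumes: int,
    tr_s: float,
    state_covariances: list[np.ndarray],
    dwell_volumes: float,
    seed: int | None = None,
) -> tuple[NetworkTimecourseSet, np.ndarray]:
    """Zero-mean Gaussian network time courses under a switching covariance.

    The hidden state dwells a geometric number of volumes (mean
    ``dwell_volumes``) in each covariance regime.  Returns the time-course set
    and the per-volume state sequence.
    """
    if n_volumes <= 0:
        raise ValueError("n_volumes must be positive")
    if not state_covariances:
        raise ValueError("need at least one state covariance")
    covs = [np.asarray(c, dtype=float) for c in state_covariances]
    p = covs[0].shape[0]
    chols = []
    for i, c in enumerate(covs):
        if c.shape != (p, p) or not np.allclose(c, c.T):
            raise ValueError(f"state covariance {i} is not symmetric {p}x{p}")
        try:
            chols.append(np.linalg.cholesky(c))
        except np.linalg.LinAlgError as err:
            raise ValueError(f"state covariance {i} is not positive definite") from err
    if not dwell_volumes >= 1:
        raise ValueError("dwell_volumes must be >= 1")
    rng = np.random.default_rng(seed)
    states = _sample_labels(len(covs), n_volumes, 1.0 / dwell_volumes, rng)
    z = rng.standard_normal((p, n_volumes))
    data = np.empty((p, n_volumes))
    for s, chol in enumerate(chols):
        idx = states == s
        data[:, idx] = chol @ z[:, idx]
    return NetworkTimecourseSet(data, tr_s), states
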