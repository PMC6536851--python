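"""Map-level primitives: global field power, GFP peaks, spatial correlation, GEV.

Global field power (GFP) at one time point is the spatial standard deviation
of the average-referenced signal across all electrodes; its local maxima are
the instants of highest field strength at which scalp topography is most
reliable, and the microstate analysis is restricted to these peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .recording import is_average_referenced

__all__ = [
    "GFPSeries",
    "compute_gfp",
    "find_gfp_peaks",
    "spatial_correlation",
    "correlation_matrix",
    "gev",
]


@dataclass
class GFPSeries:
    """Per-sample GFP values and the indices of their strict local maxima."""

    values: np.ndarray
    peak_indices: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)
        if np.any(self.values < 0):
            raise ValueError("GFP values must be nonnegative")

    @property
    def n_peaks(self) -> int:
        return self.peak_indices.size


def compute_gfp(epoch: np.ndarray, require_average_reference: bool = True) -> GFPSeries:
    """GFP series of one epoch (channels x samples).

    The value at sample ``t`` is the population standard deviation (ddof=0)
    across channels of column ``t``: with all electrodes taken as the
    population, this is the spatial SD of the average-referenced signal.
    """
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim != 2:
        raise ValueError("epoch must be 2-D (channels x samples)")
    if require_average_reference and not is_average_referenced(epoch):
        raise ValueError(
            "epoch is not average-referenced; re-reference first or pass "
            "require_average_reference=False"
        )
    values = epoch.std(axis=0, ddof=0)
    return GFPSeries(values, find_gfp_peaks(values))


def find_gfp_peaks(values: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima of a series.

    Plateaus contribute their centre sample (left-centre when the plateau has
    even length); the first and last samples are never peaks.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 3:
        raise ValueError("need a 1-D series of length >= 3")
    # scipy returns the middle of flat peaks, rounded down = left-centre
    peaks, _ = sps.find_peaks(values)
    return peaks


def _validate_map(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float).ravel()
    if m.std(ddof=0) == 0:
        raise ValueError(f"{name} has zero variance; spatial correlation undefined")
    return m


def spatial_correlation(
    map_a: np.ndarray, map_b: np.ndarray, polarity_invariant: bool = True
) -> float:
    """Pearson correlation of two maps across channels.

    With ``polarity_invariant`` the absolute value is returned, treating a
    topography and its sign-flipped version as the same state (the resting
    microstate convention).
    """
    a = _validate_map(map_a, "map_a")
    b = _validate_map(map_b, "map_b")
    if a.size != b.size:
        raise ValueError("maps must have equal channel counts")
    r = float(np.corrcoef(a, b)[0, 1])
    return abs(r) if polarity_invariant else r


def correlation_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlations across channels between rows of A and rows of B."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    na = np.linalg.norm(Ac, axis=1)
    nb = np.linalg.norm(Bc, axis=1)
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError("zero-variance map in correlation computation")
    return (Ac @ Bc.T) / np.outer(na, nb)


def gev(
    templates: np.ndarray,
    maps: np.ndarray,
    gfp: np.ndarray | None = None,
    labels: np.ndarray | None = None,
    polarity_invariant: bool = True,
) -> float:
    """Global explained variance of a template set on a collection of maps.

    GEV = sum_t (GFP_t * corr(map_t, template_of(t)))^2 / sum_t GFP_t^2.
    With ``labels`` the stated assignment is used; otherwise each map is
    assigned to its best template (highest |correlation|).
    """
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    if maps.shape[0] == 0:
        raise ValueError("empty map set")
    templates = np.atleast_2d(np.asarray(templates, dtype=float))
    if gfp is None:
        gfp = maps.std(axis=1, ddof=0)
    gfp = np.asarray(gfp, dtype=float)
    C = correlation_matrix(maps, templates)
    if polarity_invariant:
        C = np.abs(C)
    if labels is None:
        corr = C.max(axis=1)
    else:
        labels = np.asarray(labels, dtype=int)
        corr = C[np.arange(maps.shape[0]), labels]
    denom = float(np.sum(gfp**2))
    if denom == 0:
        raise ValueError("all maps have zero GFP")
    return float(np.sum((gfp * corr) ** 2) / denom)
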