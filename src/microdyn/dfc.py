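"""Sliding-window dynamic functional connectivity and its variability.

Connectivity between network time courses is the Pearson correlation inside
a tapered sliding window (rectangle convolved with a Gaussian, the usual
sliding-window dFC convention: 22 volumes, step 1, sigma = 3 volumes by
default).  The variability of a connection is the standard deviation of its
windowed correlation over time; a subcortical target network (basal ganglia
or thalamus) is summarized by the mean variability over all its connections,
which is then correlated with mean microstate duration across subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .synthetic import NetworkTimecourseSet

__all__ = [
    "WindowedConnectivity",
    "DFCVariability",
    "window_taper",
    "sliding_window_dfc",
    "dfc_variability",
    "microstate_dfc_correlation",
]


@dataclass
class WindowedConnectivity:
    corr: np.ndarray  # (n_windows, n_networks, n_networks); NaN = undefined
    window_volumes: int
    step_volumes: int
    taper_sigma: float
    network_names: list[str] = field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return self.corr.shape[0]

    @property
    def n_networks(self) -> int:
        return self.corr.shape[1]


@dataclass
class DFCVariability:
    sd: np.ndarray  # (n_networks, n_networks) SD of windowed connectivity
    network_means: np.ndarray  # mean SD over each network's connections
    window_volumes: int
    step_volumes: int
    taper_sigma: float
    network_names: list[str] = field(default_factory=list)

    def target_mean(self, target) -> float:
        """Mean variability over all connections involving ``target``."""
        i = (self.network_names.index(target)
             if isinstance(target, str) else int(target))
        return float(self.network_means[i])


def window_taper(window_volumes: int, taper_sigma: float) -> np.ndarray:
    """Rectangle of the window length convolved with a Gaussian, renormalized.

    ``taper_sigma=0`` gives a plain rectangular window.
    """
    if window_volumes < 2:
        raise ValueError("window must span at least 2 volumes")
    rect = np.ones(window_volumes)
    if taper_sigma > 0:
        radius = int(np.ceil(4 * taper_sigma))
        x = np.arange(-radius, radius + 1)
        g = np.exp(-0.5 * (x / taper_sigma) ** 2)
        g /= g.sum()
        full = np.convolve(rect, g)
        mid = full.size // 2
        half = window_volumes // 2
        rect = full[mid - half : mid - half + window_volumes]
    return rect / rect.sum()


def sliding_window_dfc(
    tcs: NetworkTimecourseSet,
    window_volumes: int = 22,
    step_volumes: int = 1,
    taper_sigma: float = 3.0,
) -> WindowedConnectivity:
    """Tapered-window Pearson correlation for every network pair.

    Windows advance by ``step_volumes`` until the window no longer fits:
    n_windows = (n_volumes - window) // step + 1.  A zero-variance segment
    makes the affected pairs NaN (undefined) with a warning, never silently 0.
    """
    if window_volumes > tcs.n_volumes:
        raise ValueError("window longer than the time course")
    if step_volumes < 1:
        raise ValueError("step must be >= 1")
    w = window_taper(window_volumes, taper_sigma)
    n_win = (tcs.n_volumes - window_volumes) // step_volumes + 1
    p = tcs.n_networks
    corr = np.empty((n_win, p, p))
    degenerate = False
    for wi in range(n_win):
        seg = tcs.data[:, wi * step_volumes : wi * step_volumes + window_volumes]
        mu = seg @ w
        d = seg - mu[:, None]
        cov = (d * w) @ d.T
        var = np.diag(cov).copy()
        ms = (seg**2) @ w  # relative threshold: numerically constant segments
        bad = var <= 1e-12 * np.maximum(ms, 1e-300)
        if bad.any():
            degenerate = True
            var[bad] = np.nan
        denom = np.sqrt(np.outer(var, var))
        corr[wi] = cov / denom
    if degenerate:
        warnings.warn(
            "zero-variance window segment(s): affected pairs reported as NaN",
            stacklevel=2,
        )
    return WindowedConnectivity(corr, window_volumes, step_volumes, taper_sigma,
                                list(tcs.network_names))


def dfc_variability(
    windowed: WindowedConnectivity,
    max_undefined_fraction: float = 0.0,
    fisher_z: bool = False,
) -> DFCVariability:
    """SD over windows of every pairwise connectivity, plus per-network means.

    ``fisher_z`` applies arctanh before taking the SD.  Fails when the
    fraction of undefined windows of any pair exceeds
    ``max_undefined_fraction``.
    """
    if windowed.n_windows < 3:
        raise ValueError("need at least 3 windows to estimate variability")
    c = windowed.corr
    frac_nan = np.isnan(c).mean(axis=0)
    off = ~np.eye(windowed.n_networks, dtype=bool)
    if np.any(frac_nan[off] > max_undefined_fraction):
        raise ValueError(
            "undefined windowed correlations exceed the tolerated fraction "
            f"({max_undefined_fraction})"
        )
    vals = np.arctanh(np.clip(c, -1 + 1e-12, 1 - 1e-12)) if fisher_z else c
    sd = np.nanstd(vals, axis=0, ddof=1)
    np.fill_diagonal(sd, 0.0)
    means = np.array([
        sd[i, off[i]].mean() for i in range(windowed.n_networks)
    ])
    return DFCVariability(sd, means, windowed.window_volumes,
                          windowed.step_volumes, windowed.taper_sigma,
                          list(windowed.network_names))


def microstate_dfc_correlation(
    table: pd.DataFrame,
    duration_col: str,
    variability_cols: list[str],
    correction: str = "fdr",
    subject_col: str | None = None,
) -> pd.DataFrame:
    """Pearson correlation of mean microstate duration with dFC variability.

    One row per variability column (the target-network mean and/or each
    connection separately); per-connection p-values are corrected across the
    declared family (``fdr`` = Benjamini-Hochberg, or ``bonferroni``).
    """
    if correction not in ("fdr", "bonferroni"):
        raise ValueError("correction must be 'fdr' or 'bonferroni'")
    if subject_col is not None and table[subject_col].duplicated().any():
        dupes = table.loc[table[subject_col].duplicated(), subject_col].tolist()
        raise ValueError(f"duplicated subject ids: {dupes}")
    rows = []
    for col in variability_cols:
        sub = table[[duration_col, col]].dropna()
        if len(sub) < 4:
            raise ValueError(
                f"fewer than 4 paired subjects for {col} ({len(sub)})"
            )
        if sub[col].nunique() < 2 or sub[duration_col].nunique() < 2:
            warnings.warn(
                f"{col}: constant variable, correlation undefined", stacklevel=2
            )
            rows.append((col, len(sub), np.nan, np.nan))
            continue
        r = sstats.pearsonr(sub[duration_col].to_numpy(), sub[col].to_numpy())
        rows.append((col, len(sub), float(r.statistic), float(r.pvalue)))
    out = pd.DataFrame(rows, columns=["connection", "n", "r", "p"])
    out["p_corrected"] = np.nan
    valid = out["p"].notna()
    if valid.any():
        method = "fdr_bh" if correction == "fdr" else "bonferroni"
        out["p_corrected"] = out["p_corrected"].astype(float)
        out.loc[valid, "p_corrected"] = multipletests(
            out.loc[valid, "p"].to_numpy(), method=method
        )[1]
    return out
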