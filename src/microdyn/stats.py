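"""Topographic and tabular statistics: TANOVA, correlations with FDR control,
and generic permutation/rank utilities.

TANOVA (topographic analysis of variance) is a nonparametric randomization
test on *global map dissimilarity* -- the root-mean-square channel difference
between strength-normalized, average-referenced maps.  The design here has a
within-subject factor (microstate class) and a between-subject factor
(group); main effects permute the corresponding factor labels and the
interaction permutes group labels of double-centred residual maps.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "gmd",
    "tanova",
    "correlate_with_fdr",
    "rank_permutation_test",
    "linear_residualize",
]


def _norm_map(m: np.ndarray) -> np.ndarray:
    """Unit-GFP version of a map; a flat map is returned unchanged (zero)."""
    sd = m.std(axis=-1, keepdims=True)
    return np.divide(m, sd, out=np.zeros_like(m), where=sd > 0)


def gmd(map_a: np.ndarray, map_b: np.ndarray) -> float:
    """Global map dissimilarity: RMS channel difference of unit-GFP maps."""
    a = _norm_map(np.asarray(map_a, dtype=float))
    b = _norm_map(np.asarray(map_b, dtype=float))
    return float(np.sqrt(np.mean((a - b) ** 2)))


def _level_stat(level_means: np.ndarray, grand: np.ndarray) -> np.ndarray:
    """Sum over factor levels of GMD(level mean, grand mean).

    ``level_means``: (..., L, C); broadcast over leading permutation axes.
    """
    lm = _norm_map(level_means)
    return np.sqrt(np.mean((lm - grand) ** 2, axis=-1)).sum(axis=-1)


def tanova(
    maps: np.ndarray,
    groups,
    n_perm: int = 1000,
    seed: int | None = None,
    effects: tuple[str, ...] = ("class", "group", "interaction"),
) -> dict:
    """Two-factor randomization TANOVA on per-subject, per-class maps.

    Parameters
    ----------
    maps : (n_subjects, n_classes, n_channels)
        One average-referenced map per subject and class (class labels must
        already be aligned across subjects, e.g. to the group mean maps).
    groups : (n_subjects,) group label per subject.
    n_perm : permutations per effect (add-one p-values).

    Returns
    -------
    dict with observed effect sizes and p-values per requested effect.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 3:
        raise ValueError("maps must be (subjects, classes, channels)")
    bad = np.flatnonzero(~np.isfinite(maps).all(axis=(1, 2)))
    if bad.size:
        raise ValueError(f"subjects with missing class maps: {bad.tolist()}")
    groups = np.asarray(groups)
    S, K, C = maps.shape
    if groups.shape != (S,):
        raise ValueError("one group label per subject required")
    uniq = np.unique(groups)
    if uniq.size < 2 and "group" in effects:
        raise ValueError("group effect needs >= 2 groups")
    X = _norm_map(maps)  # scale invariance: every map unit GFP
    rng = np.random.default_rng(seed)
    out: dict = {"n_perm": n_perm, "seed": seed}

    group_idx = [np.flatnonzero(groups == g) for g in uniq]

    def perm_group_stat(data: np.ndarray, grand: np.ndarray) -> tuple[float, np.ndarray]:
        """data: (S, L, C) subject-level level-maps; permute subjects."""
        obs = float(np.sum([
            _level_stat(data[gi].mean(axis=0), grand) for gi in group_idx
        ]))
        perms = np.array([rng.permutation(S) for _ in range(n_perm)])
        null = np.zeros(n_perm)
        for gi in group_idx:
            lm = data[perms[:, gi]].mean(axis=1)  # (n_perm, L, C)
            null += _level_stat(lm, grand)
        return obs, null

    if "class" in effects:
        grand = _norm_map(X.mean(axis=(0, 1)))
        class_means = X.mean(axis=0)  # (K, C)
        obs = float(_level_stat(class_means, grand))
        null = np.zeros(n_perm)
        idx = np.tile(np.arange(K), (n_perm, S, 1))
        idx = rng.permuted(idx, axis=2)  # independent class shuffle per subject
        acc = np.zeros((n_perm, K, C))
        for s in range(S):
            acc += X[s][idx[:, s]]
        null = _level_stat(acc / S, grand)
        out["class"] = {
            "stat": obs, "p": float((1 + np.sum(null >= obs)) / (1 + n_perm)),
        }

    if "group" in effects:
        subj_mean = X.mean(axis=1)[:, None, :]  # (S, 1, C): one level
        grand = _norm_map(subj_mean.mean(axis=0))
        obs, null = perm_group_stat(subj_mean, grand)
        out["group"] = {
            "stat": obs, "p": float((1 + np.sum(null >= obs)) / (1 + n_perm)),
        }

    if "interaction" in effects:
        # double-centred residuals: remove both main effects, then permute
        # group membership of whole subjects
        subj_mean = X.mean(axis=1, keepdims=True)
        class_mean = X.mean(axis=0, keepdims=True)
        grand_raw = X.mean(axis=(0, 1), keepdims=True)
        R = X - subj_mean - class_mean + grand_raw  # (S, K, C)
        zero = np.zeros(C)
        obs = float(np.sum([
            _level_stat(R[gi].mean(axis=0), zero) for gi in group_idx
        ]))
        perms = np.array([rng.permutation(S) for _ in range(n_perm)])
        null = np.zeros(n_perm)
        for gi in group_idx:
            lm = R[perms[:, gi]].mean(axis=1)
            null += _level_stat(lm, zero)
        out["interaction"] = {
            "stat": obs, "p": float((1 + np.sum(null >= obs)) / (1 + n_perm)),
        }
    return out


def correlate_with_fdr(
    table: pd.DataFrame,
    x_vars: list[str],
    y_vars: list[str],
    method: str = "spearman",
) -> pd.DataFrame:
    """Pairwise-complete correlations with Benjamini-Hochberg adjustment.

    Every (x, y) pair forms one member of the declared family; pairs with a
    constant variable are reported with NaN and excluded from the family
    with a warning.  Requires >= 4 complete pairs per correlation.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    fn = sstats.spearmanr if method == "spearman" else sstats.pearsonr
    rows = []
    for x in x_vars:
        for y in y_vars:
            sub = table[[x, y]].dropna()
            if len(sub) < 4:
                raise ValueError(
                    f"pair ({x}, {y}) has only {len(sub)} complete observations (< 4)"
                )
            if sub[x].nunique() < 2 or sub[y].nunique() < 2:
                warnings.warn(
                    f"pair ({x}, {y}) involves a constant variable; "
                    "correlation undefined, excluded from the FDR family",
                    stacklevel=2,
                )
                rows.append((x, y, len(sub), np.nan, np.nan))
                continue
            res = fn(sub[x].to_numpy(), sub[y].to_numpy())
            rows.append((x, y, len(sub), float(res.statistic), float(res.pvalue)))
    out = pd.DataFrame(rows, columns=["x", "y", "n", "coef", "p"])
    out["p_fdr"] = np.nan
    valid = out["p"].notna()
    if valid.any():
        out.loc[valid, "p_fdr"] = multipletests(
            out.loc[valid, "p"].to_numpy(), method="fdr_bh"
        )[1]
    return out


def rank_permutation_test(
    values: np.ndarray,
    groups: np.ndarray,
    n_perm: int = 10000,
    seed: int | None = None,
) -> dict:
    """Two-group, two-sided permutation test on the rank-sum statistic."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if uniq.size != 2:
        raise ValueError("exactly two groups required")
    ranks = sstats.rankdata(values)
    mask = groups == uniq[0]
    n0 = int(mask.sum())
    expected = ranks.mean() * n0
    obs = abs(float(ranks[mask].sum()) - expected)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(ranks)
        if abs(float(perm[:n0].sum()) - expected) >= obs:
            count += 1
    return {
        "stat_rank_sum_dev": obs,
        "p": (1 + count) / (1 + n_perm),
        "n_perm": n_perm,
        "groups": uniq.tolist(),
    }


def linear_residualize(y: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    """Residuals of y after removing a single linear covariate (plumbing)."""
    y = np.asarray(y, dtype=float)
    c = np.asarray(covariate, dtype=float)
    A = np.column_stack([np.ones_like(c), c])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return y - A @ beta
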