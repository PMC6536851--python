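"""Topographic atomize & agglomerate hierarchical clustering (TAAHC) and
model selection for the number of microstate classes.

TAAHC starts from singleton clusters and repeatedly *atomizes* the worst
cluster -- the one whose members correlate least with their own centroid --
reassigning each freed map to the surviving cluster with the highest
|spatial correlation|.  Because clusters only ever disappear one at a time,
a solution is available at every cluster count on the way down, and the
optimal count is chosen afterwards by a bank of cluster-validity criteria
voting on the GFP-weighted unexplained-variance curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .maps import correlation_matrix, gev
from .recording import unit_gfp

__all__ = [
    "TaahcSolution",
    "taahc",
    "select_k_meta",
    "group_mean_maps",
]


@dataclass
class TaahcSolution:
    """One clustering solution: templates, per-map assignment, explained variance."""

    k: int
    templates: np.ndarray  # (k, n_channels), unit GFP, average-referenced
    labels: np.ndarray  # (n_maps,)
    gev: float
    polarity_invariant: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.gev <= 1.0 + 1e-12:
            raise ValueError(f"GEV must lie in [0, 1], got {self.gev}")


def _centroid(members: np.ndarray, polarity_invariant: bool) -> np.ndarray:
    """Cluster template: first principal component of the member maps under
    polarity invariance (sign-consistent centroid), sign-aligned mean
    otherwise; unit-GFP normalized."""
    m, c = members.shape
    if m == 1:
        v = members[0]
    elif polarity_invariant:
        # leading principal axis via the smaller of the two Gram matrices
        if m < c:
            g = members @ members.T
            _, vecs = np.linalg.eigh(g)
            v = members.T @ vecs[:, -1]
        else:
            s = members.T @ members
            _, vecs = np.linalg.eigh(s)
            v = vecs[:, -1]
    else:
        ref = members[0]
        signs = np.sign(members @ ref)
        signs[signs == 0] = 1.0
        v = (members * signs[:, None]).mean(axis=0)
    # deterministic sign: strongest channel positive
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    sd = v.std(ddof=0)
    if sd == 0:
        raise ValueError("degenerate (flat) cluster centroid")
    return v / sd


def taahc(
    maps: np.ndarray,
    k_min: int = 1,
    k_max: int = 12,
    polarity_invariant: bool = True,
    gfp: np.ndarray | None = None,
) -> dict[int, TaahcSolution]:
    """Cluster maps bottom-up, recording a solution at every k in [k_min, k_max].

    Parameters
    ----------
    maps : (n_maps, n_channels)
        Average-referenced maps (e.g. topographies at GFP peaks).  They are
        normalized to unit GFP internally; the original GFP values (or the
        ``gfp`` argument) weight the explained-variance bookkeeping.
    """
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    n_maps, n_ch = maps.shape
    if not 1 <= k_min <= k_max:
        raise ValueError("need 1 <= k_min <= k_max")
    if k_max > n_maps:
        raise ValueError(f"k_max={k_max} exceeds the number of maps ({n_maps})")
    if gfp is None:
        gfp = maps.std(axis=1, ddof=0)
    gfp = np.asarray(gfp, dtype=float)
    X = unit_gfp(maps)  # mean-zero rows, std 1 -> corr(a, b) = a.b / n_ch

    # one slot per initial singleton; dead slots get +inf quality
    cent_arr = X.copy()
    members: dict[int, np.ndarray] = {i: np.array([i]) for i in range(n_maps)}
    quality = np.ones(n_maps)
    alive = np.ones(n_maps, dtype=bool)
    n_alive = n_maps

    def cluster_quality(idx: np.ndarray, c: np.ndarray) -> float:
        r = (X[idx] @ c) / n_ch
        return float(np.sum(np.abs(r) if polarity_invariant else r))

    solutions: dict[int, TaahcSolution] = {}

    def record() -> None:
        slots = np.flatnonzero(alive)
        labels = np.empty(n_maps, dtype=int)
        for ci, slot in enumerate(slots):
            labels[members[slot]] = ci
        templates = cent_arr[slots].copy()
        g = gev(templates, maps, gfp=gfp, labels=labels,
                polarity_invariant=polarity_invariant)
        solutions[len(slots)] = TaahcSolution(len(slots), templates, labels, g,
                                              polarity_invariant)

    masked_quality = quality.copy()
    while True:
        if k_min <= n_alive <= k_max:
            record()
        if n_alive <= k_min:
            break
        np.copyto(masked_quality, quality)
        masked_quality[~alive] = np.inf
        worst = int(np.argmin(masked_quality))
        freed = members.pop(worst)
        alive[worst] = False
        n_alive -= 1
        act = np.flatnonzero(alive)
        r = (X[freed] @ cent_arr[act].T) / n_ch
        if polarity_invariant:
            r = np.abs(r)
        dest = act[np.argmax(r, axis=1)]
        for slot in np.unique(dest):
            members[slot] = np.concatenate([members[slot], freed[dest == slot]])
            cent_arr[slot] = _centroid(X[members[slot]], polarity_invariant)
            quality[slot] = cluster_quality(members[slot], cent_arr[slot])
    return solutions


def _unexplained(sol: TaahcSolution, maps: np.ndarray, gfp: np.ndarray) -> float:
    """GFP^2-weighted unexplained topographic variance of one solution."""
    C = correlation_matrix(maps, sol.templates)
    corr = C[np.arange(maps.shape[0]), sol.labels]
    if sol.polarity_invariant:
        corr = np.abs(corr)
    return float(np.sum(gfp**2 * (1.0 - corr**2)))


def select_k_meta(
    solutions: dict[int, TaahcSolution],
    maps: np.ndarray,
    gfp: np.ndarray | None = None,
    criteria: tuple[str, ...] = ("kl", "cv", "dispersion"),
) -> int:
    """Choose the number of microstate classes by a criterion-bank median vote.

    Each enabled criterion votes an optimal k from the solution range; the
    lower median of the votes is returned (ties favour the smaller k).

    Criteria
    --------
    ``kl``
        Normalized Krzanowski-Lai: ratio of successive dimension-corrected
        drops of the unexplained-variance curve W(k); votes the k after which
        the improvement collapses.
    ``cv``
        Cross-validation criterion: residual noise variance inflated by the
        per-class degrees-of-freedom penalty ((C-1)/(C-1-k))^2; votes argmin.
    ``dispersion``
        Curvature of the normalized dispersion ratio W(k)/W_total; votes the
        elbow (argmax of the discrete second difference).
    """
    if len(criteria) < 2:
        raise ValueError("need at least 2 criteria enabled for a meta-criterion vote")
    unknown = set(criteria) - {"kl", "cv", "dispersion"}
    if unknown:
        raise ValueError(f"unknown criteria: {sorted(unknown)}")
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    n_maps, n_ch = maps.shape
    if gfp is None:
        gfp = maps.std(axis=1, ddof=0)
    gfp = np.asarray(gfp, dtype=float)
    ks = sorted(solutions)
    k_lo, k_hi = ks[0], ks[-1]
    if ks != list(range(k_lo, k_hi + 1)):
        raise ValueError("solutions must cover a contiguous k range")
    W = {k: _unexplained(solutions[k], maps, gfp) for k in ks}
    total = float(np.sum(gfp**2))
    # no structure beyond k_lo classes: everything already explained
    if W[k_lo] <= 1e-10 * max(total, 1.0):
        return k_lo

    eps = 1e-300
    votes: list[int] = []
    interior = [k for k in ks if k_lo < k < k_hi]
    if "kl" in criteria:
        def diff(k: int) -> float:
            p = n_ch
            return (k - 1) ** (2.0 / p) * W[k - 1] - k ** (2.0 / p) * W[k]
        if interior:
            scores = [abs(diff(k)) / max(abs(diff(k + 1)), eps) for k in interior]
            votes.append(interior[int(np.argmax(scores))])
        else:
            votes.append(k_lo)
    if "cv" in criteria:
        cv_ks = [k for k in ks if k < n_ch - 1]
        cv = [
            (n_ch * W[k] / (n_maps * (n_ch - 1)))
            * ((n_ch - 1) / (n_ch - 1 - k)) ** 2
            for k in cv_ks
        ]
        votes.append(cv_ks[int(np.argmin(cv))])
    if "dispersion" in criteria:
        if interior:
            curv = [(W[k - 1] - 2.0 * W[k] + W[k + 1]) / max(W[k_lo], eps)
                    for k in interior]
            votes.append(interior[int(np.argmax(curv))])
        else:
            votes.append(k_lo)
    votes.sort()
    return votes[(len(votes) - 1) // 2]


def group_mean_maps(
    subject_templates: list[np.ndarray],
    polarity_invariant: bool = True,
    max_iter: int = 100,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Average subject template sets into group maps by permutation alignment.

    Class labels are arbitrary within each subject, so each subject's classes
    are iteratively relabelled (and, under polarity invariance, sign-flipped)
    to maximize the total |spatial correlation| with the current mean maps;
    the mean is then recomputed, until no relabelling changes.

    Returns
    -------
    mean_maps : (k, n_channels) unit-GFP group maps
    permutations : per-subject arrays p with ``aligned = subject[p]``
    """
    if not subject_templates:
        raise ValueError("need at least one subject")
    sets = [unit_gfp(np.atleast_2d(np.asarray(t, dtype=float)))
            for t in subject_templates]
    k = sets[0].shape[0]
    if any(s.shape != sets[0].shape for s in sets):
        raise ValueError("all subjects must share k and channel count")
    mean = sets[0].copy()
    perms = [np.arange(k) for _ in sets]
    signs = [np.ones(k) for _ in sets]
    for _ in range(max_iter):
        changed = False
        aligned = []
        for si, s in enumerate(sets):
            c = correlation_matrix(mean, s)  # (k_mean, k_subject)
            score = np.abs(c) if polarity_invariant else c
            row, col = linear_sum_assignment(-score)
            p = col[np.argsort(row)]
            sgn = np.sign(c[np.arange(k), p]) if polarity_invariant else np.ones(k)
            sgn[sgn == 0] = 1.0
            if not np.array_equal(p, perms[si]) or not np.array_equal(sgn, signs[si]):
                changed = True
            perms[si], signs[si] = p, sgn
            aligned.append(s[p] * sgn[:, None])
        mean = unit_gfp(np.mean(aligned, axis=0))
        if not changed:
            break
    return mean, perms
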