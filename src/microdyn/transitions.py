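"""Microstate transition probabilities and a randomization test for syntax.

Transitions are counted between consecutive distinct, non-truncated runs
within each epoch (never across epochs).  The expected matrix under
independent syntax assigns each destination a probability proportional to its
run count among the remaining classes; non-randomness is tested by shuffling
the order of runs, which preserves every class's run count exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .segment import UNASSIGNED, Segmentation, extract_runs

__all__ = [
    "TransitionMatrix",
    "transition_matrix",
    "transition_randomness_test",
    "run_sequences",
]


@dataclass
class TransitionMatrix:
    observed: np.ndarray  # (k, k) row-stochastic, zero diagonal; NaN rows = missing
    expected: np.ndarray  # same shape, independence expectation
    counts: np.ndarray  # raw transition counts
    n_transitions: int


def run_sequences(seg: Segmentation) -> list[np.ndarray]:
    """Per-epoch sequences of non-truncated run labels, in temporal order."""
    seqs: dict[int, list[int]] = {e: [] for e in range(seg.n_epochs)}
    for e, lab, _length, trunc in extract_runs(seg):
        if not trunc and lab != UNASSIGNED:
            seqs[e].append(lab)
    return [np.array(seqs[e], dtype=int) for e in range(seg.n_epochs)]


def _count_transitions(seqs: list[np.ndarray], k: int) -> np.ndarray:
    counts = np.zeros((k, k))
    for s in seqs:
        if s.size < 2:
            continue
        src, dst = s[:-1], s[1:]
        keep = src != dst  # shuffled sequences may hold adjacent repeats
        np.add.at(counts, (src[keep], dst[keep]), 1.0)
    return counts


def _expected_probs(run_counts: np.ndarray) -> np.ndarray:
    """expected(i, j) = occurrence_j / sum_{l != i} occurrence_l, zero diagonal."""
    k = run_counts.size
    exp = np.zeros((k, k))
    for i in range(k):
        denom = run_counts.sum() - run_counts[i]
        if denom > 0:
            exp[i] = run_counts / denom
        exp[i, i] = 0.0
    return exp


def transition_matrix(seg: Segmentation) -> TransitionMatrix:
    """Observed and independence-expected transition probabilities."""
    k = seg.n_classes
    seqs = run_sequences(seg)
    present = np.unique(np.concatenate([s for s in seqs if s.size] or [np.array([], int)]))
    if present.size < 2:
        raise ValueError("need at least 2 microstate classes present")
    counts = _count_transitions(seqs, k)
    row = counts.sum(axis=1)
    observed = np.full((k, k), np.nan)
    nz = row > 0
    observed[nz] = counts[nz] / row[nz, None]
    if not np.all(nz):
        warnings.warn(
            f"classes {np.flatnonzero(~nz).tolist()} have no outgoing "
            "transitions; their rows are reported as missing",
            stacklevel=2,
        )
    run_counts = np.zeros(k)
    for s in seqs:
        np.add.at(run_counts, s, 1.0)
    expected = _expected_probs(run_counts)
    return TransitionMatrix(observed, expected, counts, int(counts.sum()))


def _collapse(s: np.ndarray) -> np.ndarray:
    """Merge adjacent equal run labels (a rearrangement that puts two runs of
    one class side by side is the same physical sequence with merged runs)."""
    if s.size < 2:
        return s
    return s[np.concatenate([[True], np.diff(s) != 0])]


def _stats(seqs: list[np.ndarray], k: int) -> tuple[float, float]:
    """(max-cell |obs - exp|, chi-square-style global sum) for one set of
    run sequences, against the sequences' own independence expectation."""
    counts = _count_transitions(seqs, k)
    run_counts = np.zeros(k)
    for s in seqs:
        np.add.at(run_counts, s, 1.0)
    expected = _expected_probs(run_counts)
    row = counts.sum(axis=1)
    exp_counts = expected * row[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        obs = np.where(row[:, None] > 0, counts / np.maximum(row[:, None], 1.0), 0.0)
        chi_cells = np.where(exp_counts > 0,
                             (counts - exp_counts) ** 2
                             / np.where(exp_counts > 0, exp_counts, 1.0),
                             0.0)
    max_dev = float(np.max(np.abs(obs - expected)))
    return max_dev, float(chi_cells.sum())


def transition_randomness_test(
    seg: Segmentation,
    n_shuffles: int = 1000,
    seed: int | None = None,
) -> dict:
    """Randomization test of non-random microstate syntax.

    The null shuffles the order of runs within each epoch ``n_shuffles``
    times -- preserving per-class run counts up to the merging of runs that a
    permutation places side by side -- and compares the maximal cell
    deviation |observed - expected| and a chi-square-style global sum against
    the shuffled ensemble.  Both statistics are computed identically for the
    observed and every shuffled sequence (each against its own independence
    expectation).  p-values follow the add-one permutation convention and are
    never exactly 0.
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    k = seg.n_classes
    seqs = run_sequences(seg)
    n_runs = int(sum(s.size for s in seqs))
    if n_runs < 10:
        raise ValueError(f"too few runs ({n_runs} < 10) for a shuffling null")
    obs_max, obs_chi = _stats(seqs, k)
    rng = np.random.default_rng(seed)
    ge_max = 0
    ge_chi = 0
    for _ in range(n_shuffles):
        # permute run order (preserving class run counts), then merge runs a
        # permutation happens to place side by side, so every null draw is a
        # bona fide run sequence scored exactly like the observed one
        shuffled = [_collapse(rng.permutation(s)) for s in seqs]
        m, c = _stats(shuffled, k)
        if m >= obs_max:
            ge_max += 1
        if c >= obs_chi:
            ge_chi += 1
    return {
        "stat_max_cell": obs_max,
        "stat_global": obs_chi,
        "p_max_cell": (1 + ge_max) / (1 + n_shuffles),
        "p_global": (1 + ge_chi) / (1 + n_shuffles),
        "n_shuffles": n_shuffles,
        "n_runs": n_runs,
        "seed": seed,
    }
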