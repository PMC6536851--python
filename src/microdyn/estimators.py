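"""scikit-learn style estimators wrapping the microstate core.

:class:`TAAHCClustering` is a clusterer over topographic maps;
:class:`MicrostateSegmenter` is the full subject-level path: GFP peaks ->
TAAHC -> optimal-k meta-criterion -> back-fitting.  Both follow sklearn
conventions (``fit``, ``predict``, ``get_params``/``set_params``, fitted
attributes with trailing underscores) and compose with sklearn tooling;
the module-level functions in :mod:`microdyn.cluster` and
:mod:`microdyn.segment` are the underlying implementation.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .cluster import group_mean_maps, select_k_meta, taahc
from .maps import compute_gfp, correlation_matrix
from .recording import EpochSet, unit_gfp
from .segment import Segmentation, backfit, temporal_metrics

__all__ = ["TAAHCClustering", "MicrostateSegmenter"]


class TAAHCClustering(ClusterMixin, BaseEstimator):
    """Atomize-and-agglomerate hierarchical clustering of topographies.

    Parameters
    ----------
    n_clusters : int or "auto"
        Cluster count; ``"auto"`` selects k over ``k_range`` by the
        meta-criterion vote.
    k_range : (int, int)
        Inclusive search range for auto selection (also the range of
        recorded solutions).
    polarity_invariant : bool
        Treat a map and its negation as the same class (resting microstate
        convention).

    Attributes
    ----------
    labels_ : (n_maps,) cluster assignment of the training maps
    cluster_centers_ : (k, n_channels) unit-GFP templates
    n_clusters_ : selected k
    gev_ : global explained variance of the selected solution
    solutions_ : dict k -> :class:`microdyn.cluster.TaahcSolution`
    """

    def __init__(
        self,
        n_clusters: int | str = "auto",
        k_range: tuple[int, int] = (1, 12),
        polarity_invariant: bool = True,
    ):
        self.n_clusters = n_clusters
        self.k_range = k_range
        self.polarity_invariant = polarity_invariant

    def fit(self, X, y=None, sample_weight=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.n_clusters == "auto":
            k_min, k_max = self.k_range
        else:
            k_min = k_max = int(self.n_clusters)
        self.solutions_ = taahc(
            X, k_min=k_min, k_max=k_max,
            polarity_invariant=self.polarity_invariant, gfp=sample_weight,
        )
        if self.n_clusters == "auto":
            self.n_clusters_ = select_k_meta(self.solutions_, X, gfp=sample_weight)
        else:
            self.n_clusters_ = int(self.n_clusters)
        sol = self.solutions_[self.n_clusters_]
        self.labels_ = sol.labels
        self.cluster_centers_ = sol.templates
        self.gev_ = sol.gev
        return self

    def predict(self, X):
        """Assign new maps to the nearest template by |spatial correlation|."""
        c = correlation_matrix(np.atleast_2d(np.asarray(X, dtype=float)),
                               self.cluster_centers_)
        if self.polarity_invariant:
            c = np.abs(c)
        return np.argmax(c, axis=1)


class MicrostateSegmenter(BaseEstimator):
    """Subject-level microstate model: learn templates, then segment epochs.

    ``fit`` collects the topographies at GFP peaks of all epochs, clusters
    them with TAAHC and (optionally) picks k with the meta-criterion;
    ``predict`` back-fits the learned (or externally supplied group)
    templates to epochs, returning a :class:`~microdyn.segment.Segmentation`.
    """

    def __init__(
        self,
        n_states: int | str = "auto",
        k_range: tuple[int, int] = (1, 12),
        polarity_invariant: bool = True,
        fit_mode: str = "peaks_interpolated",
    ):
        self.n_states = n_states
        self.k_range = k_range
        self.polarity_invariant = polarity_invariant
        self.fit_mode = fit_mode

    @staticmethod
    def _peak_maps(epochs: EpochSet) -> tuple[np.ndarray, np.ndarray]:
        maps, gfps = [], []
        for e in range(epochs.n_epochs):
            ep = epochs.epochs[e]
            g = compute_gfp(ep)
            if g.n_peaks:
                maps.append(ep[:, g.peak_indices].T)
                gfps.append(g.values[g.peak_indices])
        if not maps:
            raise ValueError("no GFP peaks found in any epoch")
        return np.vstack(maps), np.concatenate(gfps)

    def fit(self, epochs: EpochSet, y=None):
        maps, gfp = self._peak_maps(epochs)
        clu = TAAHCClustering(
            n_clusters=self.n_states, k_range=self.k_range,
            polarity_invariant=self.polarity_invariant,
        ).fit(maps, sample_weight=gfp)
        self.n_states_ = clu.n_clusters_
        self.templates_ = clu.cluster_centers_
        self.gev_ = clu.gev_
        self.solutions_ = clu.solutions_
        self.n_peak_maps_ = maps.shape[0]
        return self

    def predict(self, epochs: EpochSet, templates: np.ndarray | None = None
                ) -> Segmentation:
        t = self.templates_ if templates is None else unit_gfp(templates)
        return backfit(t, epochs, mode=self.fit_mode,
                       polarity_invariant=self.polarity_invariant)

    def fit_predict(self, epochs: EpochSet, y=None) -> Segmentation:
        return self.fit(epochs).predict(epochs)

    def metrics(self, epochs: EpochSet, templates: np.ndarray | None = None):
        """Convenience: segment and summarize in one call."""
        return temporal_metrics(self.predict(epochs, templates))


def fit_cohort_models(
    epoch_sets: list[EpochSet],
    n_states: int | str = "auto",
    k_range: tuple[int, int] = (1, 12),
    polarity_invariant: bool = True,
) -> list[MicrostateSegmenter]:
    """Fit one subject-level model per epoch set (shared settings)."""
    return [
        MicrostateSegmenter(n_states=n_states, k_range=k_range,
                            polarity_invariant=polarity_invariant).fit(ep)
        for ep in epoch_sets
    ]


def cohort_group_maps(
    models: list[MicrostateSegmenter], polarity_invariant: bool = True
) -> np.ndarray:
    """Permutation-aligned mean maps across fitted subject models."""
    mean, _ = group_mean_maps([m.templates_ for m in models],
                              polarity_invariant=polarity_invariant)
    return mean
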