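"""Empirical multivariate variogram over geographic distance classes.

The empirical multivariate variogram at distance class h is

    gamma(h) = sum_i (1 / (2 n_h)) * sum_{pairs (a,b) in class} (x_ia - x_ib)^2

summed over species i, where x are Hellinger-transformed abundances and n_h
is the number of sample pairs whose separation falls in the class.  Summed
over classes that cover all pairs (pair-count weighted), it equals the total
sample variance s².  Only classes below half the maximum extent (h_max / 2)
are used by default: beyond that distance, central stations can no longer
contribute pairs, which biases the estimate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .dataio import CommunityMatrix, StationTable

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceClassing",
    "EmpiricalVariogram",
    "build_classes",
    "all_pairs_classing",
    "empirical_variogram",
    "pair_semivariances",
]

#: Candidate class widths (km); the narrowest giving at most
#: :data:`MAX_CLASSES` classes under the cutoff is chosen automatically.
STANDARD_INTERVALS_KM = (0.25, 0.50, 0.75)
MAX_CLASSES = 12
MIN_PAIRS_RECOMMENDED = 30


@dataclass
class DistanceClassing:
    """Binning of station pairs into geographic distance classes.

    Classes are half-open ``[lower, upper)``, disjoint, ordered, and extend
    up to the cutoff (default ``h_max / 2``).  ``pair_lists[k]`` holds the
    ``(a, b)`` integer index pairs (a < b, positions in ``sample_ids``)
    whose Euclidean separation falls in class k.
    """

    sample_ids: list
    interval_km: float
    cutoff_km: float
    h_max: float
    class_edges: np.ndarray  # shape (n_classes + 1,)
    pair_lists: list  # list of (n_k, 2) int arrays

    @property
    def n_classes(self) -> int:
        return len(self.pair_lists)

    @property
    def class_centers(self) -> np.ndarray:
        """Arithmetic midpoints of the class edges."""
        return 0.5 * (self.class_edges[:-1] + self.class_edges[1:])

    @property
    def n_pairs(self) -> np.ndarray:
        return np.array([len(p) for p in self.pair_lists], dtype=int)


@dataclass
class EmpiricalVariogram:
    """Per-class semivariance gamma(h) with its standard error.

    ``gamma`` is NaN for classes holding no pairs (missing, not zero);
    ``se`` is the standard deviation over pairs of the per-pair semivariance
    divided by sqrt(n_h), NaN where fewer than 2 pairs.
    """

    classing: DistanceClassing
    gamma: np.ndarray
    se: np.ndarray

    def usable(self) -> np.ndarray:
        """Boolean mask of classes with at least one pair."""
        return self.classing.n_pairs > 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "class_center_km": self.classing.class_centers,
            "n_pairs": self.classing.n_pairs,
            "gamma": self.gamma,
            "se": self.se,
        })


def choose_interval(h_max: float, cutoff_km: float,
                    candidates=STANDARD_INTERVALS_KM,
                    max_classes: int = MAX_CLASSES) -> float:
    """Pick the narrowest standard class width giving <= max_classes classes.

    Falls back to ``cutoff / max_classes`` when even the widest candidate
    would produce too many classes (tiny study areas scale the other way:
    the narrowest candidate is used when all candidates give one class).
    """
    for w in sorted(candidates):
        if int(np.ceil(cutoff_km / w)) <= max_classes:
            return float(w)
    return float(cutoff_km / max_classes)


def build_classes(stations: StationTable, interval_km: float | None = None,
                  cutoff_km: float | None = None) -> DistanceClassing:
    """Bin all station pairs into distance classes up to the cutoff.

    Parameters
    ----------
    stations
        Station coordinates (projected km).
    interval_km
        Class width; ``None`` selects automatically from 0.25/0.50/0.75 km,
        the narrowest giving at most 12 classes under the cutoff.
    cutoff_km
        Maximum usable distance; defaults to ``h_max / 2``.

    Warns when a class holds fewer than 30 pairs (variance estimates for
    such classes are unstable) and when pairs fall beyond the cutoff.
    """
    if stations.n_stations < 2:
        raise ValueError("need at least 2 stations")
    dists = pdist(stations.coords)
    h_max = float(dists.max())
    if h_max <= 0:
        raise ValueError("all stations are colocated; distances are all zero")
    if cutoff_km is None:
        cutoff_km = h_max / 2.0
    if cutoff_km <= 0:
        raise ValueError("cutoff must be positive")
    if interval_km is None:
        interval_km = choose_interval(h_max, cutoff_km)
    if interval_km <= 0:
        raise ValueError("interval_km must be positive")

    n_classes = int(np.ceil(cutoff_km / interval_km - 1e-12))
    edges = interval_km * np.arange(n_classes + 1, dtype=float)

    n = stations.n_stations
    ii, jj = np.triu_indices(n, k=1)
    # pdist ordering matches triu_indices(k=1)
    idx = np.floor(dists / interval_km).astype(int)
    pair_lists = []
    for k in range(n_classes):
        sel = idx == k
        pair_lists.append(np.column_stack([ii[sel], jj[sel]]))
    n_beyond = int(np.sum(idx >= n_classes))
    if n_beyond:
        logger.info("%d pair(s) beyond the %.3g km cutoff excluded",
                    n_beyond, cutoff_km)
        if n_beyond == len(dists):
            warnings.warn("every station pair lies beyond the cutoff; "
                          "no usable distance classes", UserWarning,
                          stacklevel=2)

    classing = DistanceClassing(sample_ids=list(stations.sample_ids),
                                interval_km=float(interval_km),
                                cutoff_km=float(cutoff_km), h_max=h_max,
                                class_edges=edges, pair_lists=pair_lists)
    thin = [k for k, np_k in enumerate(classing.n_pairs)
            if 0 < np_k < MIN_PAIRS_RECOMMENDED]
    if thin:
        warnings.warn(
            f"classes {thin} hold fewer than {MIN_PAIRS_RECOMMENDED} pairs; "
            "their gamma estimates are unstable", UserWarning, stacklevel=2)
    return classing


def all_pairs_classing(stations: StationTable) -> DistanceClassing:
    """A single class covering every pair — used for totals and partitions."""
    n = stations.n_stations
    ii, jj = np.triu_indices(n, k=1)
    h_max = stations.h_max
    return DistanceClassing(sample_ids=list(stations.sample_ids),
                            interval_km=h_max, cutoff_km=h_max,
                            h_max=h_max,
                            class_edges=np.array([0.0, h_max]),
                            pair_lists=[np.column_stack([ii, jj])])


def pair_semivariances(matrix: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    """Per-pair semivariance: sum over species of (x_a - x_b)^2 / 2."""
    if len(pairs) == 0:
        return np.empty(0)
    diff = matrix[pairs[:, 0]] - matrix[pairs[:, 1]]
    return 0.5 * np.einsum("ij,ij->i", diff, diff)


def _gamma_se(matrix: np.ndarray, classing: DistanceClassing):
    gamma = np.full(classing.n_classes, np.nan)
    se = np.full(classing.n_classes, np.nan)
    for k, pairs in enumerate(classing.pair_lists):
        if len(pairs) == 0:
            continue
        sv = pair_semivariances(matrix, pairs)
        gamma[k] = sv.mean()
        if len(sv) > 1:
            se[k] = sv.std(ddof=1) / np.sqrt(len(sv))
    return gamma, se


def empirical_variogram(community: CommunityMatrix,
                        classing: DistanceClassing,
                        matrix: np.ndarray | None = None) -> EmpiricalVariogram:
    """Empirical multivariate variogram of the Hellinger abundances.

    Parameters
    ----------
    community
        Provides the sample ids and, by default, the Hellinger matrix.
    classing
        Distance classes built from the matching stations.
    matrix
        Optional alternative samples-x-variables matrix (e.g. fitted or
        residual values from an ordination) aligned to the same ids.
    """
    if list(community.sample_ids) != list(classing.sample_ids):
        raise ValueError("community and classing sample ids do not match")
    if matrix is None:
        matrix = community.hellinger
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] != community.n_samples:
        raise ValueError("matrix row count does not match sample ids")
    gamma, se = _gamma_se(matrix, classing)
    return EmpiricalVariogram(classing=classing, gamma=gamma, se=se)
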