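"""Input tables, Hellinger transform, and total community variance.

Two containers are shared by every stage of the pipeline: a
:class:`CommunityMatrix` (sample-by-species abundances plus their Hellinger
transform) and a :class:`StationTable` (projected station coordinates in km,
a categorical habitat-province label, and continuous environmental
covariates).  Both are thin wrappers over pandas DataFrames, aligned on a
common ordered list of sample ids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CommunityMatrix",
    "StationTable",
    "hellinger_transform",
    "total_variance",
    "read_site",
]


def hellinger_transform(counts: np.ndarray) -> np.ndarray:
    """Square root of within-sample relative abundance.

    For sample *a* and species *i*, ``x_ia = sqrt(count_ia / rowtotal_a)``.
    Each transformed row is a unit vector in the squared sense, so Euclidean
    distances between rows are Hellinger distances between community
    compositions.

    Parameters
    ----------
    counts
        2-D array of nonnegative abundances, samples in rows.

    Raises
    ------
    ValueError
        If any count is negative or any row total is zero.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts must be a 2-D samples x species array")
    if np.any(counts < 0):
        raise ValueError("abundances must be nonnegative")
    totals = counts.sum(axis=1)
    if np.any(totals <= 0):
        bad = np.nonzero(totals <= 0)[0]
        raise ValueError(f"zero row total for sample row(s) {bad.tolist()}; "
                         "empty samples must be excluded first")
    return np.sqrt(counts / totals[:, None])


def total_variance(hellinger: np.ndarray) -> float:
    """Total sample variance s² of a Hellinger-transformed matrix.

    Sum over species of the (n-1)-denominator sample variance of each
    transformed column.  Equals the pair-count-weighted mean of the
    empirical multivariate variogram when the distance classes cover all
    sample pairs.
    """
    hellinger = np.asarray(hellinger, dtype=float)
    if hellinger.shape[0] < 2:
        raise ValueError("total variance needs at least 2 samples")
    return float(hellinger.var(axis=0, ddof=1).sum())


@dataclass
class CommunityMatrix:
    """Site-by-species abundances with their Hellinger view.

    Attributes
    ----------
    sample_ids : list of str
        Ordered sample identifiers (rows).
    species_ids : list of str
        Ordered species identifiers (columns).
    counts : ndarray
        Nonnegative abundances, shape (n_samples, n_species).
    hellinger : ndarray
        Hellinger-transformed abundances, same shape.
    """

    sample_ids: list
    species_ids: list
    counts: np.ndarray
    hellinger: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.sample_ids), len(self.species_ids)):
            raise ValueError("counts shape does not match id lists")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if self.hellinger is None:
            self.hellinger = hellinger_transform(self.counts)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def total_variance(self) -> float:
        """s², the total Hellinger-scale community variance."""
        return total_variance(self.hellinger)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CommunityMatrix":
        """Build from a DataFrame with sample-id index and species columns.

        Samples with zero total abundance and species observed nowhere are
        dropped with a logged warning — the Hellinger transform is undefined
        for an empty sample, and an all-zero species contributes nothing to
        any variance.
        """
        values = frame.to_numpy(dtype=float)
        row_tot = values.sum(axis=1)
        empty = row_tot <= 0
        if empty.any():
            dropped = list(frame.index[empty])
            logger.warning("dropping %d sample(s) with zero total abundance: %s",
                           len(dropped), dropped)
            frame = frame.loc[~empty]
            values = values[~empty]
        absent = values.sum(axis=0) <= 0
        if absent.any():
            logger.warning("dropping %d species observed in no sample",
                           int(absent.sum()))
            frame = frame.loc[:, ~absent]
        return cls(sample_ids=list(frame.index),
                   species_ids=list(frame.columns),
                   counts=frame.to_numpy(dtype=float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids,
                            columns=self.species_ids)


@dataclass
class StationTable:
    """Station coordinates, province labels and environmental covariates.

    Coordinates must be projected planar, in kilometres; geographic
    (lon/lat) coordinates are not supported because every distance in the
    analysis is a planar Euclidean distance in km.
    """

    sample_ids: list
    x_km: np.ndarray
    y_km: np.ndarray
    province: pd.Series  # categorical label per station
    environment: pd.DataFrame  # continuous covariates, index = sample_ids

    def __post_init__(self) -> None:
        self.x_km = np.asarray(self.x_km, dtype=float)
        self.y_km = np.asarray(self.y_km, dtype=float)
        n = len(self.sample_ids)
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if self.x_km.shape != (n,) or self.y_km.shape != (n,):
            raise ValueError("coordinate arrays must match sample ids")
        if not (np.all(np.isfinite(self.x_km)) and np.all(np.isfinite(self.y_km))):
            raise ValueError("coordinates must be finite")

    @property
    def n_stations(self) -> int:
        return len(self.sample_ids)

    @property
    def coords(self) -> np.ndarray:
        return np.column_stack([self.x_km, self.y_km])

    @property
    def h_max(self) -> float:
        """Maximum extent: largest pairwise distance between stations."""
        from scipy.spatial.distance import pdist

        if self.n_stations < 2:
            raise ValueError("h_max needs at least 2 stations")
        return float(pdist(self.coords).max())

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "StationTable":
        """Build from a DataFrame indexed by sample id.

        Expects columns ``x_km``, ``y_km``, ``province``; any remaining
        numeric columns are treated as environmental covariates.
        """
        for col in ("x_km", "y_km", "province"):
            if col not in frame.columns:
                raise ValueError(f"stations table missing required column {col!r}")
        env_cols = [c for c in frame.columns
                    if c not in ("x_km", "y_km", "province")]
        env = frame[env_cols].apply(pd.to_numeric, errors="coerce")
        return cls(sample_ids=list(frame.index),
                   x_km=frame["x_km"].to_numpy(dtype=float),
                   y_km=frame["y_km"].to_numpy(dtype=float),
                   province=frame["province"].astype(str),
                   environment=env)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"x_km": self.x_km, "y_km": self.y_km},
                           index=self.sample_ids)
        out["province"] = self.province.to_numpy()
        return pd.concat([out, self.environment], axis=1)


def _read_table(path) -> pd.DataFrame:
    """Read a CSV/TSV with the first column as the sample-id index."""
    sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    frame = pd.read_csv(path, sep=sep, index_col=0)
    frame.index = frame.index.astype(str)
    return frame


def read_site(community_path, stations_path) -> tuple[CommunityMatrix, StationTable]:
    """Load and align the community and station tables for one site.

    Both files are delimited text with a header row and sample ids in the
    first column.  The two tables are aligned on the intersection of their
    sample ids, preserving the community table's order; unmatched ids are
    dropped with a logged report.

    Returns
    -------
    (CommunityMatrix, StationTable)
        Aligned on identical, identically ordered sample ids.
    """
    comm_frame = _read_table(community_path)
    stat_frame = _read_table(stations_path)
    if comm_frame.index.has_duplicates:
        raise ValueError("duplicate sample ids in community table")
    if stat_frame.index.has_duplicates:
        raise ValueError("duplicate sample ids in stations table")
    try:
        comm_frame = comm_frame.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric abundance cell: {exc}") from exc

    community = CommunityMatrix.from_frame(comm_frame)

    shared = [sid for sid in community.sample_ids if sid in set(stat_frame.index)]
    dropped_comm = sorted(set(community.sample_ids) - set(shared))
    dropped_stat = sorted(set(stat_frame.index) - set(shared))
    if dropped_comm:
        logger.warning("community samples absent from stations, dropped: %s",
                       dropped_comm)
    if dropped_stat:
        logger.warning("stations absent from community, dropped: %s", dropped_stat)
    if not shared:
        raise ValueError("no sample ids shared between community and stations")

    community = CommunityMatrix.from_frame(community.to_frame().loc[shared])
    stations = StationTable.from_frame(stat_frame.loc[community.sample_ids])
    return community, stations
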