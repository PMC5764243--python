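"""Redundancy analysis (RDA) with AICc forward selection and province merging.

RDA here is ordinary least squares of each column of the centered
Hellinger-transformed community matrix on a common explanatory design
(with intercept), followed by an eigendecomposition of the covariance of
the fitted values.  The canonical eigenvalues, expressed as fractions of
the total community variance s², measure explained community variation.

Model search follows two deterministic procedures:

* forward selection — at each step add the candidate variable with the
  largest conditional gain in explained variance, record the AICc of every
  step, and truncate the sequence at the minimum-AICc prefix;
* province merging — a greedy agglomeration over the categorical province
  labels that repeatedly merges the pair of groups whose merger costs the
  least explained variance, returning the grouping with minimum AICc along
  the path.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import CommunityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ExplanatoryDesign",
    "RDAModel",
    "fit_rda",
    "forward_select",
    "merge_provinces",
    "aicc_rda",
    "province_indicators",
    "standardize",
]


def standardize(columns: pd.DataFrame) -> pd.DataFrame:
    """z-standardize continuous covariates (columns with >2 distinct values)."""
    out = columns.astype(float).copy()
    for col in out.columns:
        vals = out[col]
        uniq = vals.dropna().unique()
        if set(np.unique(uniq)).issubset({0.0, 1.0}):
            continue  # leave 0/1 indicators alone
        sd = vals.std(ddof=1)
        if sd > 0:
            out[col] = (vals - vals.mean()) / sd
    return out


def province_indicators(labels: pd.Series,
                        merge_map: dict | None = None) -> pd.DataFrame:
    """Binary 1/0 indicator columns, one per (possibly merged) province.

    Every province keeps its own indicator — no reference level is dropped,
    mirroring selection over individual province variables; collinearity of
    the full set is handled by the rank rule in :func:`fit_rda`.
    """
    labels = pd.Series(labels).astype(str)
    if merge_map:
        labels = labels.map(lambda p: merge_map.get(p, p))
    dummies = pd.get_dummies(labels, prefix="province", prefix_sep="_")
    return dummies.astype(float)


@dataclass
class ExplanatoryDesign:
    """Named explanatory columns (standardized covariates + 0/1 indicators)."""

    variables: pd.DataFrame
    merge_map: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = self.variables
        const = [c for c in v.columns if v[c].nunique(dropna=False) <= 1]
        if const:
            logger.warning("dropping constant design column(s): %s", const)
            self.variables = v.drop(columns=const)

    @property
    def n_columns(self) -> int:
        return self.variables.shape[1]

    def matrix(self) -> np.ndarray:
        return self.variables.to_numpy(dtype=float)


@dataclass
class RDAModel:
    """Fitted RDA: decomposition of the centered community matrix."""

    design: ExplanatoryDesign
    sample_ids: list
    Y_centered: np.ndarray
    fitted: np.ndarray
    residual: np.ndarray
    eigenvalues: np.ndarray  # canonical eigenvalues, descending, variance units
    total_variance: float  # s²
    rank: int  # effective number of design columns used
    dropped_columns: list = field(default_factory=list)

    @property
    def explained_variance(self) -> float:
        """Sum of canonical eigenvalues (Hellinger² variance units)."""
        return float(self.eigenvalues.sum())

    @property
    def explained_fraction(self) -> float:
        if self.total_variance <= 0:
            return 0.0
        return self.explained_variance / self.total_variance

    @property
    def aicc(self) -> float:
        return aicc_rda(self)


def _drop_to_full_rank(X: np.ndarray, names: list) -> tuple[np.ndarray, list, list]:
    """Greedily drop later columns that are linear combinations of earlier ones."""
    kept_idx: list[int] = []
    dropped: list[str] = []
    for j in range(X.shape[1]):
        trial = X[:, kept_idx + [j]]
        if np.linalg.matrix_rank(trial, tol=1e-9) > len(kept_idx):
            kept_idx.append(j)
        else:
            dropped.append(names[j])
    return X[:, kept_idx], [names[i] for i in kept_idx], dropped


def fit_rda(community: CommunityMatrix, design: ExplanatoryDesign) -> RDAModel:
    """Redundancy analysis of the Hellinger matrix on an explanatory design.

    Each column-centered species column is regressed (OLS, with intercept)
    on the design; the canonical eigenvalues are the nonzero eigenvalues of
    the fitted matrix's covariance (denominator n-1).  Collinear design
    columns are dropped with a warning rather than raising.
    """
    Y = community.hellinger - community.hellinger.mean(axis=0, keepdims=True)
    n = community.n_samples
    names = list(design.variables.columns)
    X = design.matrix()
    if X.shape[0] != n:
        raise ValueError("design rows do not match community samples")

    Xc = X - X.mean(axis=0, keepdims=True)  # intercept absorbed by centering
    dropped: list[str] = []
    if Xc.shape[1]:
        Xc, kept, dropped = _drop_to_full_rank(Xc, names)
        if dropped:
            warnings.warn(f"rank-deficient design; dropped column(s) {dropped}",
                          UserWarning, stacklevel=2)
    rank = Xc.shape[1]
    if n <= rank + 1:
        raise ValueError("too few samples for the number of design columns")

    if rank == 0:
        fitted = np.zeros_like(Y)
    else:
        beta, *_ = np.linalg.lstsq(Xc, Y, rcond=None)
        fitted = Xc @ beta
    residual = Y - fitted

    # canonical eigenvalues: eigenvalues of cov(fitted), at most `rank` nonzero
    cov = fitted.T @ fitted / (n - 1)
    eig = np.linalg.eigvalsh(cov)[::-1]
    eig = np.clip(eig, 0.0, None)
    eig = eig[:max(rank, 1)] if rank else np.zeros(1)

    return RDAModel(design=design, sample_ids=list(community.sample_ids),
                    Y_centered=Y, fitted=fitted, residual=residual,
                    eigenvalues=eig,
                    total_variance=community.total_variance,
                    rank=rank, dropped_columns=dropped)


def aicc_rda(model: RDAModel) -> float:
    """AICc of an RDA fit.

    AICc = n ln(RSS/n) + 2K + 2K(K+1)/(n-K-1) with RSS the residual sum of
    squares pooled over species, n the number of samples and K the number
    of effective design columns + 2 (intercept and residual variance).
    """
    n = len(model.sample_ids)
    k = model.rank + 2
    if n - k - 1 <= 0:
        raise ValueError("AICc undefined: n - K - 1 <= 0")
    rss = float(np.sum(model.residual ** 2))
    if rss <= 0:
        rss = 1e-300
    return float(n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1))


def forward_select(community: CommunityMatrix, candidates: pd.DataFrame,
                   standardize_continuous: bool = True
                   ) -> tuple[RDAModel, pd.DataFrame]:
    """AICc-guided forward selection of explanatory variables.

    At each step the candidate with the largest conditional eigenvalue gain
    (additional explained variance, as a fraction of s²) enters; ties break
    by column name.  The full path is recorded, then truncated at the
    minimum-AICc prefix (possibly empty).

    Returns
    -------
    (RDAModel, DataFrame)
        The minimum-AICc model and the selection trace with columns
        ``step, variable, eigenvalue, cumulative, aicc``.
    """
    if candidates.shape[1] == 0:
        raise ValueError("need at least one candidate variable")
    cand = standardize(candidates) if standardize_continuous else candidates.copy()

    n = community.n_samples
    selected: list[str] = []
    remaining = sorted(cand.columns)
    rows = []
    prev_frac = 0.0
    s2 = community.total_variance

    baseline = fit_rda(community, ExplanatoryDesign(
        variables=pd.DataFrame(index=cand.index)))
    best_aicc = aicc_rda(baseline)
    best_len = 0

    while remaining and n - (len(selected) + 1 + 2) - 1 > 0:
        gains = []
        for name in remaining:
            model = fit_rda(community,
                            ExplanatoryDesign(variables=cand[selected + [name]]))
            gains.append((model.explained_fraction - prev_frac, name, model))
        gains.sort(key=lambda t: (-t[0], t[1]))
        gain, name, model = gains[0]
        selected.append(name)
        remaining.remove(name)
        prev_frac = model.explained_fraction
        try:
            step_aicc = aicc_rda(model)
        except ValueError:
            break
        rows.append({"step": len(selected), "variable": name,
                     "eigenvalue": gain, "cumulative": prev_frac,
                     "aicc": step_aicc})
        if step_aicc < best_aicc:
            best_aicc = step_aicc
            best_len = len(selected)

    trace = pd.DataFrame(rows,
                         columns=["step", "variable", "eigenvalue",
                                  "cumulative", "aicc"])
    final = fit_rda(community, ExplanatoryDesign(
        variables=cand[selected[:best_len]]))
    return final, trace


def _grouping_aicc(community: CommunityMatrix, labels: pd.Series,
                   merge_map: dict) -> tuple[float, float, ExplanatoryDesign]:
    design = ExplanatoryDesign(variables=province_indicators(labels, merge_map),
                               merge_map=dict(merge_map))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # expected collinearity
        model = fit_rda(community, design)
    return aicc_rda(model), model.explained_fraction, design


def merge_provinces(community: CommunityMatrix, province_labels,
                    max_groups: int | None = None) -> ExplanatoryDesign:
    """Greedy agglomerative search for the most parsimonious province grouping.

    Starting from singleton groups, repeatedly merge the pair of groups whose
    merger least decreases the RDA explained variance, evaluating each
    configuration's AICc; the configuration with minimum AICc along the merge
    path is returned (its ``merge_map`` maps original labels to group names).
    Provinces with fewer than 2 stations are first merged into the group with
    the nearest mean Hellinger composition.
    """
    labels = pd.Series(province_labels).astype(str)
    labels.index = range(len(labels))
    if labels.nunique() < 2:
        raise ValueError("need at least 2 provinces to search mergers")

    merge_map = {p: p for p in sorted(labels.unique())}

    def groups() -> dict:
        out: dict[str, list] = {}
        for orig, grp in merge_map.items():
            out.setdefault(grp, []).append(orig)
        return out

    def group_members(grp_name: str) -> np.ndarray:
        members = [p for p, g in merge_map.items() if g == grp_name]
        return labels.isin(members).to_numpy()

    # fold singleton-station provinces into the compositionally nearest group
    counts = labels.value_counts()
    tiny = [p for p in sorted(counts.index) if counts[p] < 2]
    for p in tiny:
        if len(set(merge_map.values())) < 2:
            break
        centroid_p = community.hellinger[group_members(merge_map[p])].mean(axis=0)
        best_g, best_d = None, np.inf
        for g in sorted(set(merge_map.values())):
            if g == merge_map[p]:
                continue
            cg = community.hellinger[group_members(g)].mean(axis=0)
            d = float(np.linalg.norm(centroid_p - cg))
            if d < best_d:
                best_g, best_d = g, d
        warnings.warn(f"province {p!r} has < 2 stations; merged into {best_g!r}",
                      UserWarning, stacklevel=2)
        target = merge_map[p]
        for orig, g in merge_map.items():
            if g == target:
                merge_map[orig] = best_g

    def n_groups(mapping: dict) -> int:
        return len(set(mapping.values()))

    def eligible(mapping: dict) -> bool:
        return max_groups is None or n_groups(mapping) <= max_groups

    best_aicc, best_design = np.inf, None
    if eligible(merge_map):
        best_aicc, _, best_design = _grouping_aicc(community, labels, merge_map)

    # walk the greedy merge path down to 2 groups, keeping the min-AICc stop
    while n_groups(merge_map) > 2:
        names = sorted(groups())
        best_trial, best_frac = None, -np.inf
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                trial = dict(merge_map)
                merged_name = "+".join(sorted(set(
                    names[i].split("+") + names[j].split("+"))))
                for orig, g in trial.items():
                    if g in (names[i], names[j]):
                        trial[orig] = merged_name
                _, frac, _ = _grouping_aicc(community, labels, trial)
                if frac > best_frac:
                    best_frac, best_trial = frac, trial
        merge_map = best_trial
        a, _, design = _grouping_aicc(community, labels, merge_map)
        if eligible(merge_map) and a < best_aicc:
            best_aicc, best_design = a, design
    if best_design is None:  # max_groups stricter than the whole path
        _, _, best_design = _grouping_aicc(community, labels, merge_map)
    return best_design
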