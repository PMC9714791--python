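"""Decorrelated ranked feature analysis (DRFA).

Correlated behavioral features are standardized, whitened by the pooled
within-group covariance, and the resulting statistically independent
components are ranked by between-group separation.  Groups of subjects
are then modelled as Gaussian "clouds" in the retained space, and pairs
of clouds are compared through a Discrimination Index that rescales
distributional overlap onto [50, 100]:

    index = 50 + 50 * (1 - OVL)

where OVL is the Bhattacharyya coefficient between the two fitted
Gaussians (1 for identical clouds -> 50; 0 for fully separated -> 100).
Permutation p-values re-run the whole pipeline per label shuffle.
Treatment groups can be projected into a fixed reference space and given
per-subject rescue scores on the disease-to-control axis (disease mean
-> 0, control mean -> 100, unclipped).
"""
from __future__ import annotations

import dataclasses
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from numpy.random import default_rng
from sklearn.covariance import LedoitWolf

__all__ = [
    "FeatureMatrix",
    "DRFSpace",
    "Cloud",
    "Discrimination",
    "ProjectedGroup",
    "fit_drf_space",
    "fit_cloud",
    "discrimination_index",
    "permutation_pvalue",
    "project_group",
    "rescue_score",
]


@dataclasses.dataclass(frozen=True)
class FeatureMatrix:
    """Subjects x features data with one group label per subject."""

    values: np.ndarray
    group_labels: np.ndarray
    feature_names: Tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        labels = np.asarray(self.group_labels)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "group_labels", labels)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        if values.ndim != 2:
            raise ValueError("values must be 2-D (subjects x features)")
        if values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names must match the number of columns")
        if values.shape[0] != labels.shape[0]:
            raise ValueError("one group label is required per subject")
        if np.isnan(values).any():
            raise ValueError("missing values are not allowed")
        uniq, counts = np.unique(labels, return_counts=True)
        if counts.min() < 3:
            small = uniq[counts < 3]
            raise ValueError(f"every group needs >= 3 subjects; too small: {list(small)}")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, group_col: str = "group") -> "FeatureMatrix":
        features = [c for c in df.columns if c != group_col]
        return cls(
            values=df[features].to_numpy(dtype=float),
            group_labels=df[group_col].to_numpy(),
            feature_names=tuple(features),
        )

    def subset(self, labels: Sequence) -> "FeatureMatrix":
        mask = np.isin(self.group_labels, list(labels))
        return FeatureMatrix(self.values[mask], self.group_labels[mask], self.feature_names)

    @property
    def groups(self) -> Tuple:
        return tuple(np.unique(self.group_labels))


@dataclasses.dataclass(frozen=True)
class DRFSpace:
    """Fitted decorrelating transform with ranked components."""

    center: np.ndarray
    scale: np.ndarray
    transform: np.ndarray  # (n_features, k), columns in rank order
    ranking: Tuple[int, ...]
    k: int
    feature_names: Tuple[str, ...]

    def apply(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if values.ndim == 1:
            values = values[None, :]
        if values.shape[1] != self.center.shape[0]:
            raise ValueError(
                f"expected {self.center.shape[0]} features, got {values.shape[1]}"
            )
        return ((values - self.center) / self.scale) @ self.transform


@dataclasses.dataclass(frozen=True)
class Cloud:
    """Gaussian model of one subject group in the reduced space."""

    label: str
    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.cov, dtype=float)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)
        if cov.shape != (mean.size, mean.size):
            raise ValueError("cov must be square and match the mean dimension")


@dataclasses.dataclass(frozen=True)
class Discrimination:
    index: float
    pvalue: float
    n_permutations: int

    def __post_init__(self) -> None:
        if not 50.0 - 1e-9 <= self.index <= 100.0 + 1e-9:
            raise ValueError("index must lie in [50, 100]")


@dataclasses.dataclass(frozen=True)
class ProjectedGroup:
    cloud: Cloud
    distances: Dict[str, float]
    indices: Dict[str, float]


def _within_group_residuals(data: FeatureMatrix, standardized: np.ndarray) -> np.ndarray:
    resid = standardized.copy()
    for g in data.groups:
        mask = data.group_labels == g
        resid[mask] -= resid[mask].mean(axis=0)
    return resid


def fit_drf_space(
    data: FeatureMatrix,
    k: Optional[int] = None,
    shrinkage: Optional[float] = None,
) -> DRFSpace:
    """Standardize, whiten by the pooled within-group covariance, and
    rank components by between-group separation.

    shrinkage=None picks automatically: the empirical covariance when it
    is well conditioned, otherwise an analytic Ledoit-Wolf estimate.
    A numeric shrinkage in [0, 1] blends toward the identity explicitly;
    0 forces the empirical covariance and raises if it is singular.
    """
    if len(data.groups) < 2:
        raise ValueError("fitting the space requires at least two groups")
    X = data.values
    n, p = X.shape
    if k is None:
        k = p
    if k > p:
        raise ValueError(f"k={k} exceeds the number of features ({p})")
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    scale = np.where(scale > 0, scale, 1.0)
    Z = (X - center) / scale
    resid = _within_group_residuals(data, Z)
    dof = n - len(data.groups)
    if dof < 1:
        raise ValueError("not enough subjects to estimate the within-group covariance")
    S = resid.T @ resid / dof
    if shrinkage is None:
        eig = np.linalg.eigvalsh(S)
        if eig.min() <= 1e-10 * max(eig.max(), 1.0):
            S = LedoitWolf(assume_centered=True).fit(resid).covariance_ * (n / dof)
    elif shrinkage > 0:
        S = (1.0 - shrinkage) * S + shrinkage * np.trace(S) / p * np.eye(p)
    else:
        if np.linalg.eigvalsh(S).min() <= 1e-12:
            raise ValueError("singular within-group covariance; enable regularization")
    evals, evecs = np.linalg.eigh(S)
    evals = np.maximum(evals, 1e-12)
    W = evecs / np.sqrt(evals)  # whitening map: cov(Z @ W) == I
    comps = Z @ W
    # between-group sum of squares per component, about the overall mean
    overall = comps.mean(axis=0)
    bss = np.zeros(p)
    for g in data.groups:
        mask = data.group_labels == g
        diff = comps[mask].mean(axis=0) - overall
        bss += mask.sum() * diff**2
    ranking = tuple(int(i) for i in np.argsort(-bss, kind="mergesort"))
    return DRFSpace(
        center=center,
        scale=scale,
        transform=W[:, ranking[:k]],
        ranking=ranking,
        k=k,
        feature_names=data.feature_names,
    )


def fit_cloud(space: DRFSpace, values: np.ndarray, label: str = "") -> Cloud:
    """Fit the Gaussian cloud of one group in the reduced space."""
    T = space.apply(values)
    if T.shape[0] < 2:
        raise ValueError("need at least two subjects to fit a cloud")
    mean = T.mean(axis=0)
    cov = np.cov(T, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    # ridge until positive definite (degenerate groups, e.g. duplicates)
    jitter = 1e-10 * max(float(np.trace(cov)) / cov.shape[0], 1.0)
    for _ in range(40):
        try:
            np.linalg.cholesky(cov)
            break
        except np.linalg.LinAlgError:
            cov = cov + jitter * np.eye(cov.shape[0])
            jitter *= 10.0
    return Cloud(label=label, mean=mean, cov=cov)


def _bhattacharyya_coefficient(a: Cloud, b: Cloud) -> float:
    if a.mean.shape != b.mean.shape:
        raise ValueError("clouds must share dimension")
    avg = 0.5 * (a.cov + b.cov)
    diff = a.mean - b.mean
    sign, logdet_avg = np.linalg.slogdet(avg)
    if sign <= 0:
        raise np.linalg.LinAlgError("average covariance is not positive definite")
    logdet_a = np.linalg.slogdet(a.cov)[1]
    logdet_b = np.linalg.slogdet(b.cov)[1]
    db = 0.125 * float(diff @ np.linalg.solve(avg, diff))
    db += 0.5 * (logdet_avg - 0.5 * (logdet_a + logdet_b))
    return float(np.clip(np.exp(-db), 0.0, 1.0))


def discrimination_index(a: Cloud, b: Cloud) -> float:
    """Overlap-rescaled separability of two clouds, in [50, 100].

    Symmetric in its arguments; exactly 50 for identical clouds and
    approaching 100 as the overlap vanishes.
    """
    return 50.0 + 50.0 * (1.0 - _bhattacharyya_coefficient(a, b))


def _pair_index(data: FeatureMatrix, labels: np.ndarray, pair: Tuple, k, shrinkage) -> float:
    relabeled = FeatureMatrix(data.values, labels, data.feature_names)
    space = fit_drf_space(relabeled, k=k, shrinkage=shrinkage)
    a = fit_cloud(space, data.values[labels == pair[0]], str(pair[0]))
    b = fit_cloud(space, data.values[labels == pair[1]], str(pair[1]))
    return discrimination_index(a, b)


def permutation_pvalue(
    data: FeatureMatrix,
    groups: Tuple,
    n_perm: int = 1000,
    seed: Optional[int] = None,
    k: Optional[int] = None,
    shrinkage: Optional[float] = None,
) -> Discrimination:
    """Permutation test of the Discrimination Index between two groups.

    The full pipeline (space fit, cloud fit, index) is recomputed for
    every label shuffle; p = (1 + #{permuted >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if len(groups) != 2:
        raise ValueError("exactly two group labels are required")
    sub = data.subset(groups)
    observed = _pair_index(sub, sub.group_labels, tuple(groups), k, shrinkage)
    rng = default_rng(seed)
    labels = sub.group_labels.copy()
    n_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _pair_index(sub, perm, tuple(groups), k, shrinkage) >= observed:
            n_ge += 1
    return Discrimination(
        index=observed,
        pvalue=(1 + n_ge) / (n_perm + 1),
        n_permutations=n_perm,
    )


def project_group(
    space: DRFSpace,
    reference_clouds: Sequence[Cloud],
    lowered: FeatureMatrix,
) -> ProjectedGroup:
    """Map a treatment group through a fixed reference space.

    Returns its fitted cloud plus, against every reference cloud, the
    Euclidean distance between cloud means in the reduced space and the
    Discrimination Index.
    """
    if lowered.feature_names != space.feature_names:
        raise ValueError("lowered features do not match the fitted space")
    label = "+".join(str(g) for g in lowered.groups)
    cloud = fit_cloud(space, lowered.values, label)
    distances = {}
    indices = {}
    for ref in reference_clouds:
        distances[ref.label] = float(np.linalg.norm(cloud.mean - ref.mean))
        indices[ref.label] = discrimination_index(cloud, ref)
    return ProjectedGroup(cloud=cloud, distances=distances, indices=indices)


def rescue_score(
    space: DRFSpace,
    disease_cloud: Cloud,
    control_cloud: Cloud,
    lowered_values: np.ndarray,
) -> np.ndarray:
    """Per-subject rescue scores on the disease-to-control axis.

    Subjects are projected orthogonally onto the line joining the two
    cloud means and rescaled affinely: disease mean -> 0, control mean
    -> 100.  Scores outside [0, 100] are reported unclipped.
    """
    axis = control_cloud.mean - disease_cloud.mean
    denom = float(axis @ axis)
    if denom == 0.0:
        raise ValueError("disease and control cloud means coincide")
    T = space.apply(lowered_values)
    return 100.0 * ((T - disease_cloud.mean) @ axis) / denom
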