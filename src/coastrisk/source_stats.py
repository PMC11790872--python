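"""Source-identification statistics: Ward clustering and correlation PCA.

Both operate on z-score standardised data (unbiased n-1 standard
deviation).  Clustering is Ward's minimum-variance agglomeration on
Euclidean distances — the classical "ward.D2" objective where the merge
cost is the increase in total within-cluster sum of squares and the
reported height is ``sqrt(2 * delta_SS)`` — in R mode (variables, the
default: each metal's standardised profile across samples is one entity)
or Q mode (samples).  PCA is the eigendecomposition of the correlation
matrix, with Kaiser retention (eigenvalue > 1), and is preceded by the
two adequacy checks practitioners run before factor-analysing a small
survey: the Kaiser-Meyer-Olkin measure of sampling adequacy and
Bartlett's test of sphericity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import chi2

from .sample_io import SurveyTable

__all__ = [
    "LinkageTree",
    "PCAResult",
    "standardize",
    "ward_cluster",
    "pca",
    "kmo",
    "bartlett_sphericity",
]


def _as_frame(data: SurveyTable | pd.DataFrame) -> pd.DataFrame:
    if isinstance(data, SurveyTable):
        if data.has_nondetects():
            raise ValueError("substitute non-detects before multivariate analysis")
        return data.to_frame()
    return data.astype(float)


def standardize(frame: pd.DataFrame) -> pd.DataFrame:
    """Column z-scores with the unbiased (n-1) standard deviation."""
    sd = frame.std(ddof=1)
    dead = sd[(sd == 0) | sd.isna()].index.tolist()
    if dead:
        raise ValueError(f"constant (zero-variance) variable(s): {dead}")
    return (frame - frame.mean()) / sd


@dataclass(frozen=True)
class LinkageTree:
    """A Ward merge sequence over labelled leaves.

    ``linkage`` is the scipy (p-1) x 4 matrix; heights are nondecreasing
    by Ward monotonicity.
    """

    linkage: np.ndarray
    labels: tuple[str, ...]
    mode: str  # variables | samples
    standardization: str = "z-score (ddof=1) of variables"

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, k: int) -> dict[str, int]:
        """Partition the leaves into *k* groups (labels -> 1..k)."""
        if not 1 <= k <= len(self.labels):
            raise ValueError(f"k must be in [1, {len(self.labels)}]")
        flat = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(g) for g in flat)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.linkage, columns=["node_a", "node_b", "height", "size"]
        )


def ward_cluster(
    data: SurveyTable | pd.DataFrame, mode: str = "variables"
) -> LinkageTree:
    """Ward/Euclidean hierarchical clustering of a survey.

    ``variables`` (R mode) clusters analytes by their standardised
    profiles across samples; ``samples`` (Q mode) clusters samples on
    standardised variables.  Constant variables raise, since they cannot
    be standardised.
    """
    if mode not in ("variables", "samples"):
        raise ValueError(f"unknown clustering mode {mode!r}")
    z = standardize(_as_frame(data))
    if mode == "variables":
        matrix = z.to_numpy().T
        labels = tuple(z.columns)
    else:
        matrix = z.to_numpy()
        labels = tuple(str(i) for i in z.index)
    if len(labels) < 2:
        raise ValueError("need at least two entities to cluster")
    Z = hierarchy.linkage(matrix, method="ward", metric="euclidean")
    return LinkageTree(linkage=Z, labels=labels, mode=mode)


@dataclass(frozen=True)
class PCAResult:
    eigenvalues: np.ndarray  # descending; sums to p
    loadings: pd.DataFrame  # variables x components, eigvec * sqrt(eigval)
    variance_explained: np.ndarray  # percent per component
    cumulative_variance: np.ndarray
    retained: int  # Kaiser criterion: eigenvalue > 1
    kmo: float
    bartlett_chi2: float
    bartlett_p: float
    n_samples: int


def pca(data: SurveyTable | pd.DataFrame) -> PCAResult:
    """Correlation-matrix PCA with KMO, Bartlett, and Kaiser retention.

    Loadings are component correlations (eigenvector times the square
    root of the eigenvalue), reported with each component's largest-
    magnitude loading positive so the output is deterministic.
    """
    frame = _as_frame(data)
    n, p = frame.shape
    if n < 3 or p < 2:
        raise ValueError("PCA needs at least 3 samples and 2 variables")
    standardize(frame)  # raises on constant variables
    corr = frame.corr().to_numpy()
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    # sign convention: dominant loading of each component positive
    for j in range(p):
        i = int(np.argmax(np.abs(eigvec[:, j])))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    loadings = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
    explained = eigval / p * 100.0
    chi2_stat, p_value = bartlett_sphericity(corr, n)
    return PCAResult(
        eigenvalues=eigval,
        loadings=pd.DataFrame(
            loadings,
            index=frame.columns,
            columns=[f"PC{j + 1}" for j in range(p)],
        ),
        variance_explained=explained,
        cumulative_variance=np.cumsum(explained),
        retained=int(np.sum(eigval > 1.0)),
        kmo=kmo(corr),
        bartlett_chi2=chi2_stat,
        bartlett_p=p_value,
        n_samples=n,
    )


def kmo(corr: np.ndarray | pd.DataFrame) -> float:
    """Overall Kaiser-Meyer-Olkin measure of sampling adequacy.

    KMO = sum(r_ij^2) / (sum(r_ij^2) + sum(q_ij^2)) over i != j, where
    q_ij are the anti-image partial correlations
    ``-inv(R)_ij / sqrt(inv(R)_ii inv(R)_jj)``.  Requires an invertible
    correlation matrix; the result lies in [0, 1].
    """
    R = np.asarray(corr, dtype=float)
    try:
        inv = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation matrix is singular") from exc
    d = np.sqrt(np.outer(np.diag(inv), np.diag(inv)))
    partial = -inv / d
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = float(np.sum(R[off] ** 2))
    q2 = float(np.sum(partial[off] ** 2))
    return r2 / (r2 + q2)


def bartlett_sphericity(
    corr: np.ndarray | pd.DataFrame, n_samples: int
) -> tuple[float, float]:
    """Bartlett's test that the correlation matrix is an identity.

    Statistic ``-(n - 1 - (2p + 5) / 6) * ln|R|`` with p(p-1)/2 degrees
    of freedom; returns (chi2, p-value).  An identity matrix gives a
    statistic of exactly 0.
    """
    R = np.asarray(corr, dtype=float)
    p = R.shape[0]
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValueError("correlation matrix must have positive determinant")
    statistic = -(n_samples - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) / 2.0
    return float(statistic), float(chi2.sf(statistic, df))
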