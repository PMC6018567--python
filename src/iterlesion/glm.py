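"""Mass-univariate voxelwise GLM with permutation-based FWE control.

The dependent variable at each voxel is the lesion value (fuzzy abnormality
or binary indicator) across patients; the regressors are five behavioural
T-scores and lesion volume, plus an intercept.  The regressor of interest
is the composite naming score, tested one-sided in the damage-impairs
direction (greater abnormality associated with lower naming scores, i.e. a
negative slope of lesion value on the composite).

Family-wise error is controlled by the permutation distribution of the
maximum statistic (maxT), with nuisance covariates handled by the
Freedman-Lane scheme: the behavioural scores of no interest and lesion
volume are fitted first, their residuals are permuted across patients, and
the full model is refitted on each permuted dataset.  Cluster-level FWE
uses the permutation null of the maximum supra-threshold cluster extent,
computed from the same permutation stream.

`MassUnivariateGLM` is a scikit-learn style estimator operating on plain
(n_patients, n_voxels) arrays; the cohort-level functions below are thin
wrappers that handle the 3D embedding.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .cohort import Cohort, cohort_composites
from .lesion_io import AnalysisMask, ROISet

__all__ = [
    "DesignMatrix",
    "Contrast",
    "StatMap",
    "ClusterInfo",
    "ClusterSet",
    "PowerMap",
    "MassUnivariateGLM",
    "build_design_matrix",
    "default_contrast",
    "fit_voxelwise_glm",
    "permutation_maxT_fwe",
    "cluster_level_fwe",
    "threshold_and_extract_rois",
    "power_map",
]

logger = logging.getLogger(__name__)

DESIGN_COLUMNS = ("composite", "rep_n", "sem_m", "cspk_w", "writt_copy",
                  "lesion_volume", "intercept")


@dataclass
class DesignMatrix:
    """Patients x regressors matrix with fixed column order."""

    X: np.ndarray
    columns: tuple[str, ...] = DESIGN_COLUMNS

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.columns):
            raise ValueError("design shape does not match column names")

    @property
    def n(self) -> int:
        return self.X.shape[0]


@dataclass(frozen=True)
class Contrast:
    """Weight vector over design columns plus test sidedness.

    ``alternative='greater'`` tests whether the contrast of coefficients is
    positive; with the default weights (-1 on the composite score) this is
    the one-sided test for a negative lesion-composite association.
    """

    weights: tuple[float, ...]
    alternative: str = "greater"

    def __post_init__(self) -> None:
        if not any(w != 0 for w in self.weights):
            raise ValueError("contrast weights are all zero")
        if self.alternative not in ("greater", "less", "two-sided"):
            raise ValueError(f"unknown alternative {self.alternative!r}")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)


def default_contrast(columns: tuple[str, ...] = DESIGN_COLUMNS) -> Contrast:
    """-1 on the composite column: damage-impairs direction, one-sided."""
    w = [0.0] * len(columns)
    w[columns.index("composite")] = -1.0
    return Contrast(weights=tuple(w), alternative="greater")


@dataclass
class StatMap:
    """Voxelwise statistics embedded on the 3D grid (NaN outside the mask)."""

    t: np.ndarray
    df: int
    p_unc: np.ndarray
    z: np.ndarray
    mask: AnalysisMask
    affine: np.ndarray
    p_fwe: np.ndarray | None = None
    #: fitted estimator carrying the permutation nulls (set by
    #: :func:`permutation_maxT_fwe`)
    perm: "MassUnivariateGLM | None" = None


@dataclass(frozen=True)
class ClusterInfo:
    label: int
    n_voxels: int
    peak_ijk: tuple[int, int, int]
    peak_mm: tuple[float, float, float]
    peak_t: float
    peak_z: float
    peak_p_fwe: float
    cluster_p_fwe: float


@dataclass
class ClusterSet:
    """Supra-threshold clusters, sorted by peak statistic descending."""

    clusters: list[ClusterInfo] = field(default_factory=list)
    forming_p: float = 0.001
    labels: np.ndarray | None = None  # 3D grid of cluster labels

    def __len__(self) -> int:
        return len(self.clusters)

    def to_frame(self):
        import pandas as pd
        rows = [{
            "cluster": c.label,
            "peak_x_mm": c.peak_mm[0], "peak_y_mm": c.peak_mm[1],
            "peak_z_mm": c.peak_mm[2],
            "peak_Z": c.peak_z, "peak_p_fwe": c.peak_p_fwe,
            "n_voxels": c.n_voxels, "cluster_p_fwe": c.cluster_p_fwe,
        } for c in self.clusters]
        return pd.DataFrame(rows)


@dataclass
class PowerMap:
    powered: np.ndarray
    critical_t: float


# ---------------------------------------------------------------------------
# design matrix


def build_design_matrix(cohort: Cohort, center: bool = True) -> DesignMatrix:
    """Fixed-order design: composite, four nuisance tasks, lesion volume,
    intercept.

    Predictors are mean-centered by default (the intercept absorbs the
    means; t-statistics are unaffected).  Raises if the design is rank
    deficient, naming the offending column.
    """
    sc = cohort.scores_frame()
    comp = (sc["spk_pn"].to_numpy() + sc["writt_pn"].to_numpy()) / 2.0
    cols = [comp, sc["rep_n"].to_numpy(), sc["sem_m"].to_numpy(),
            sc["cspk_w"].to_numpy(), sc["writt_copy"].to_numpy(),
            cohort.lesion_volumes()]
    X = np.column_stack(cols).astype(float)
    if center:
        X = X - X.mean(axis=0, keepdims=True)
    X = np.column_stack([X, np.ones(len(cohort))])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify a culprit: a centered predictor that is (near) constant
        # or collinear with the preceding ones
        for j, name in enumerate(DESIGN_COLUMNS[:-1]):
            if np.allclose(X[:, j], X[0, j]):
                raise ValueError(f"design is rank deficient: column "
                                 f"{name!r} is constant")
        raise ValueError("design is rank deficient (collinear regressors)")
    return DesignMatrix(X=X)


# ---------------------------------------------------------------------------
# estimator


def _directional(t: np.ndarray, alternative: str) -> np.ndarray:
    if alternative == "greater":
        return t
    if alternative == "less":
        return -t
    return np.abs(t)


class MassUnivariateGLM(BaseEstimator):
    """Voxelwise OLS with Freedman-Lane maxT permutation FWE control.

    Parameters
    ----------
    contrast : sequence of float
        Weights over design columns.
    alternative : {'greater', 'less', 'two-sided'}
        Sidedness of the test on the contrast of coefficients.
    n_perm : int
        Requested number of random permutations.  When the number of
        distinct permutations (n!) does not exceed ``n_perm``, the null is
        enumerated exhaustively instead and p-values are exact.
    random_state : int or None
        Seed for the permutation stream.
    forming_p : float
        Uncorrected one-sided p defining the cluster-forming threshold.
    connectivity : {6, 18, 26}
        3D neighbourhood used for cluster extraction.

    Attributes
    ----------
    t_ : ndarray (n_voxels,)
        Contrast t-statistics.
    df_ : int
        Residual degrees of freedom, n - rank(X).
    p_unc_ : ndarray
        Uncorrected p-values per ``alternative``.
    z_ : ndarray
        Standard-normal quantiles of 1 - p_unc.
    p_fwe_ : ndarray
        maxT-corrected p-values (only if ``n_perm`` > 0 at fit time).
    maxt_null_ : ndarray (n_perm_used_,)
        Null distribution of the maximum directional statistic.
    max_cluster_null_ : ndarray
        Null distribution of the maximum supra-threshold cluster extent
        (only when a 3D mask is supplied to :meth:`fit`).
    exhaustive_ : bool
        Whether the permutation null was enumerated exhaustively.
    """

    def __init__(self, contrast=None, alternative: str = "greater",
                 n_perm: int = 5000, random_state: int | None = None,
                 forming_p: float = 0.001, connectivity: int = 26):
        self.contrast = contrast
        self.alternative = alternative
        self.n_perm = n_perm
        self.random_state = random_state
        self.forming_p = forming_p
        self.connectivity = connectivity

    # -- internals ---------------------------------------------------------

    def _structure(self) -> np.ndarray:
        if self.connectivity == 26:
            return np.ones((3, 3, 3), dtype=bool)
        if self.connectivity == 18:
            return ndimage.generate_binary_structure(3, 2)
        if self.connectivity == 6:
            return ndimage.generate_binary_structure(3, 1)
        raise ValueError("connectivity must be 6, 18 or 26")

    @staticmethod
    def _t_stats(Q: np.ndarray, a: np.ndarray, s: float, df: int,
                 Y: np.ndarray) -> np.ndarray:
        """t for contrast given the QR machinery; Y is (n, v)."""
        num = a @ Y
        qty = Q.T @ Y
        rss = np.einsum("ij,ij->j", Y, Y) - np.einsum("ij,ij->j", qty, qty)
        rss = np.maximum(rss, 0.0)
        sigma2 = rss / df
        with np.errstate(divide="ignore", invalid="ignore"):
            t = num / np.sqrt(sigma2 * s)
        # zero residual variance: +-inf by the sign of the numerator
        degenerate = sigma2 <= 1e-30
        if np.any(degenerate):
            t[degenerate] = np.where(num[degenerate] > 0, np.inf,
                                     np.where(num[degenerate] < 0,
                                              -np.inf, 0.0))
        return t

    def _perm_indices(self, n: int):
        """Yield permutation index arrays and set ``exhaustive_``."""
        n_distinct = math.factorial(n)
        if n_distinct <= self.n_perm:
            self.exhaustive_ = True
            self.n_perm_used_ = n_distinct
            return (np.array(p) for p in itertools.permutations(range(n)))
        self.exhaustive_ = False
        self.n_perm_used_ = int(self.n_perm)
        rng = np.random.default_rng(self.random_state)
        return (rng.permutation(n) for _ in range(self.n_perm))

    # -- API ---------------------------------------------------------------

    def fit(self, X: np.ndarray, Y: np.ndarray, mask: np.ndarray | None = None):
        """Fit the voxelwise GLM and build the permutation nulls.

        Parameters
        ----------
        X : ndarray (n_patients, n_regressors)
        Y : ndarray (n_patients, n_voxels)
            Lesion values at in-mask voxels.
        mask : 3D boolean ndarray, optional
            Embedding of the ``n_voxels`` columns into a 3D grid; required
            for the cluster-extent null, ignored otherwise.
        """
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        n, p = X.shape
        if Y.shape[0] != n:
            raise ValueError("X and Y disagree on the number of patients")
        if mask is not None and int(np.asarray(mask).sum()) != Y.shape[1]:
            raise ValueError("mask voxel count does not match Y columns")
        rank = np.linalg.matrix_rank(X)
        if rank < p:
            raise ValueError("singular design matrix")
        if n <= p:
            raise ValueError("need more patients than regressors")

        c = (np.asarray(self.contrast, dtype=float) if self.contrast is not None
             else np.asarray(default_contrast().weights))
        if c.shape != (p,):
            raise ValueError("contrast length does not match design columns")

        df = n - rank
        Q, R = np.linalg.qr(X)
        u = np.linalg.solve(R.T, c)
        s = float(u @ u)
        a = Q @ u

        t = self._t_stats(Q, a, s, df, Y)
        p_unc = self._p_from_t(t, df)
        self.t_, self.df_, self.p_unc_ = t, int(df), p_unc
        with np.errstate(divide="ignore"):
            self.z_ = stats.norm.isf(p_unc)
        self.n_features_in_ = p

        if self.n_perm and self.n_perm > 0:
            self._fit_permutations(X, Y, c, Q, a, s, df, mask)
        return self

    def _p_from_t(self, t: np.ndarray, df: int) -> np.ndarray:
        if self.alternative == "greater":
            return stats.t.sf(t, df)
        if self.alternative == "less":
            return stats.t.cdf(t, df)
        return 2.0 * stats.t.sf(np.abs(t), df)

    def _fit_permutations(self, X, Y, c, Q, a, s, df, mask) -> None:
        n = X.shape[0]
        nuis_cols = np.flatnonzero(c == 0)
        Z = X[:, nuis_cols]
        if Z.size:
            Qz, _ = np.linalg.qr(Z)
            fitted = Qz @ (Qz.T @ Y)
        else:
            fitted = np.zeros_like(Y)
        resid = Y - fitted

        d_obs = _directional(self.t_, self.alternative)
        self.t_forming_ = float(stats.t.isf(self.forming_p, df)
                                if self.alternative != "two-sided"
                                else stats.t.isf(self.forming_p / 2.0, df))
        structure = self._structure()
        do_cluster = mask is not None
        if do_cluster:
            mask = np.asarray(mask, dtype=bool)
            grid = np.zeros(mask.shape, dtype=bool)

        max_t, max_c = [], []
        for perm in self._perm_indices(n):
            Ystar = fitted + resid[perm]
            t_star = self._t_stats(Q, a, s, df, Ystar)
            d_star = _directional(t_star, self.alternative)
            max_t.append(d_star.max())
            if do_cluster:
                grid[:] = False
                grid[mask] = d_star > self.t_forming_
                if grid.any():
                    lab, nlab = ndimage.label(grid, structure=structure)
                    sizes = np.bincount(lab.ravel())[1:]
                    max_c.append(int(sizes.max()))
                else:
                    max_c.append(0)

        self.maxt_null_ = np.asarray(max_t)
        if do_cluster:
            self.max_cluster_null_ = np.asarray(max_c)
        self.p_fwe_ = self._null_pvalue(self.maxt_null_, d_obs)

    def _null_pvalue(self, null: np.ndarray, observed: np.ndarray) -> np.ndarray:
        """Exceedance p: exact under exhaustive enumeration (identity is one
        of the permutations), add-one Monte-Carlo otherwise."""
        observed = np.atleast_1d(observed)
        exceed = (null[None, :] >= observed[:, None]).sum(axis=1)
        if self.exhaustive_:
            return exceed / self.n_perm_used_
        return (1.0 + exceed) / (self.n_perm_used_ + 1.0)

    def cluster_p_fwe(self, size: int) -> float:
        check_is_fitted(self, "max_cluster_null_")
        return float(self._null_pvalue(self.max_cluster_null_,
                                       np.array([size]))[0])

    def fwe_critical_t(self, alpha: float = 0.05) -> float:
        """Directional statistic the observed map must reach for p_fwe <= alpha."""
        check_is_fitted(self, "maxt_null_")
        null = np.sort(self.maxt_null_)[::-1]
        if self.exhaustive_:
            k = int(np.floor(alpha * self.n_perm_used_))
        else:
            k = int(np.floor(alpha * (self.n_perm_used_ + 1))) - 1
        k = min(max(k, 0), null.size - 1)
        return float(null[k])


# ---------------------------------------------------------------------------
# cohort-level wrappers


def _embed(flat: np.ndarray, mask: np.ndarray, fill=np.nan) -> np.ndarray:
    out = np.full(mask.shape, fill, dtype=float)
    out[mask] = flat
    return out


def _masked_Y(cohort: Cohort, mask: np.ndarray) -> np.ndarray:
    return cohort.stacked_values()[:, mask].astype(float)


def fit_voxelwise_glm(cohort: Cohort, design: DesignMatrix,
                      contrast: Contrast, mask: AnalysisMask) -> StatMap:
    """OLS of lesion values on the design at every in-mask voxel.

    No multiple-comparison correction is applied here; see
    :func:`permutation_maxT_fwe`.
    """
    if mask.n_voxels == 0:
        raise ValueError("empty analysis mask")
    est = MassUnivariateGLM(contrast=list(contrast.as_array()),
                            alternative=contrast.alternative, n_perm=0)
    est.fit(design.X, _masked_Y(cohort, mask.include))
    m = mask.include
    return StatMap(t=_embed(est.t_, m), df=est.df_,
                   p_unc=_embed(est.p_unc_, m), z=_embed(est.z_, m),
                   mask=mask, affine=cohort.affine)


def permutation_maxT_fwe(cohort: Cohort, design: DesignMatrix,
                         contrast: Contrast, mask: AnalysisMask,
                         n_perm: int = 5000, seed: int | None = None,
                         forming_p: float = 0.001,
                         connectivity: int = 26) -> StatMap:
    """Voxel-level FWE-corrected p-values via Freedman-Lane maxT.

    The returned StatMap carries the fitted estimator (``.perm``) whose
    permutation stream is shared with :func:`cluster_level_fwe`.
    """
    if mask.n_voxels == 0:
        raise ValueError("empty analysis mask")
    est = MassUnivariateGLM(contrast=list(contrast.as_array()),
                            alternative=contrast.alternative,
                            n_perm=n_perm, random_state=seed,
                            forming_p=forming_p, connectivity=connectivity)
    est.fit(design.X, _masked_Y(cohort, mask.include), mask=mask.include)
    m = mask.include
    sm = StatMap(t=_embed(est.t_, m), df=est.df_,
                 p_unc=_embed(est.p_unc_, m), z=_embed(est.z_, m),
                 mask=mask, affine=cohort.affine,
                 p_fwe=_embed(est.p_fwe_, m), perm=est)
    return sm


def cluster_level_fwe(statmap: StatMap, forming_p: float = 0.001,
                      perm: MassUnivariateGLM | None = None) -> ClusterSet:
    """Extract supra-threshold clusters and assign cluster-level FWE p.

    Uses the permutation null of the maximum cluster extent computed from
    the same permutation stream as the voxel-level maxT (the estimator
    attached to the StatMap).  An empty ClusterSet is returned when no
    voxel survives the forming threshold.
    """
    est = perm if perm is not None else statmap.perm
    if est is None:
        raise ValueError("cluster-level FWE needs the permutation estimator "
                         "from permutation_maxT_fwe")
    if abs(forming_p - est.forming_p) > 1e-12:
        raise ValueError("forming_p differs from the one used to build the "
                         "cluster-extent null")
    mask = statmap.mask.include
    d = _directional(np.nan_to_num(statmap.t, nan=-np.inf),
                     est.alternative)
    supra = mask & (d > est.t_forming_)
    cs = ClusterSet(forming_p=forming_p,
                    labels=np.zeros(mask.shape, dtype=np.int32))
    if not supra.any():
        return cs
    lab, nlab = ndimage.label(supra, structure=est._structure())
    infos = []
    for k in range(1, nlab + 1):
        vox = np.argwhere(lab == k)
        dvals = d[tuple(vox.T)]
        peak = vox[int(np.argmax(dvals))]
        ijk = tuple(int(i) for i in peak)
        mm = tuple(float(x) for x in
                   (statmap.affine @ np.array([*ijk, 1.0]))[:3])
        infos.append(ClusterInfo(
            label=k, n_voxels=int(len(vox)), peak_ijk=ijk, peak_mm=mm,
            peak_t=float(statmap.t[ijk]), peak_z=float(statmap.z[ijk]),
            peak_p_fwe=float(statmap.p_fwe[ijk])
            if statmap.p_fwe is not None else np.nan,
            cluster_p_fwe=est.cluster_p_fwe(int(len(vox))),
        ))
    # relabel in descending peak statistic order
    infos.sort(key=lambda c: -c.peak_t)
    labels = np.zeros(mask.shape, dtype=np.int32)
    out = []
    for new_k, info in enumerate(infos, start=1):
        labels[lab == info.label] = new_k
        out.append(ClusterInfo(label=new_k, n_voxels=info.n_voxels,
                               peak_ijk=info.peak_ijk, peak_mm=info.peak_mm,
                               peak_t=info.peak_t, peak_z=info.peak_z,
                               peak_p_fwe=info.peak_p_fwe,
                               cluster_p_fwe=info.cluster_p_fwe))
    cs.clusters = out
    cs.labels = labels
    return cs


def threshold_and_extract_rois(statmap: StatMap, clusterset: ClusterSet,
                               alpha: float = 0.05, rule: str = "voxel",
                               connectivity: int = 26) -> ROISet:
    """Significant regions at FWE-corrected ``alpha``.

    rule='voxel': connected components of {p_fwe <= alpha} inside the mask.
    rule='cluster': all voxels of clusters with cluster-level p_fwe <= alpha.
    Labels are assigned in descending peak-t order; an empty ROISet is a
    valid outcome.
    """
    shape = statmap.mask.include.shape
    if rule == "voxel":
        if statmap.p_fwe is None:
            raise ValueError("voxel rule needs FWE-corrected p-values")
        sig = statmap.mask.include & (np.nan_to_num(statmap.p_fwe, nan=1.0)
                                      <= alpha)
        if not sig.any():
            return ROISet(labels=np.zeros(shape, dtype=np.int32))
        if connectivity == 26:
            structure = np.ones((3, 3, 3), dtype=bool)
        else:
            structure = ndimage.generate_binary_structure(
                3, {6: 1, 18: 2}[connectivity])
        lab, nlab = ndimage.label(sig, structure=structure)
        peaks = ndimage.maximum(np.nan_to_num(statmap.t, nan=-np.inf),
                                labels=lab, index=range(1, nlab + 1))
        order = np.argsort(-np.atleast_1d(peaks))
        labels = np.zeros(shape, dtype=np.int32)
        for new_k, old in enumerate(order, start=1):
            labels[lab == old + 1] = new_k
        names = {k: f"ROI_{k}" for k in range(1, nlab + 1)}
        return ROISet(labels=labels, names=names)
    if rule == "cluster":
        labels = np.zeros(shape, dtype=np.int32)
        names = {}
        new_k = 0
        for c in clusterset.clusters:  # already sorted by peak t
            if c.cluster_p_fwe <= alpha:
                new_k += 1
                labels[clusterset.labels == c.label] = new_k
                names[new_k] = f"ROI_{new_k}"
        return ROISet(labels=labels, names=names)
    raise ValueError(f"unknown ROI rule {rule!r}")


def power_map(cohort: Cohort, mask: AnalysisMask, critical_t: float,
              binarize_u: float = 0.3) -> PowerMap:
    """Best-case detectability at each voxel given the lesion sampling.

    At a voxel lesioned in k of n patients, the k lowest composite naming
    scores are assigned to the lesioned group and the two-sample pooled-
    variance t-statistic is computed; the voxel is *powered* when that
    best-case t reaches ``critical_t``.  Voxels lesioned in 0 or all
    patients carry no contrast and are never powered.
    """
    from .lesion_io import overlap_map
    comp = np.sort(cohort_composites(cohort))
    n = comp.size
    csum = np.concatenate([[0.0], np.cumsum(comp)])
    csum2 = np.concatenate([[0.0], np.cumsum(comp ** 2)])
    t_best = np.full(n + 1, -np.inf)
    for k in range(1, n):
        m1 = csum[k] / k                      # lesioned: k lowest scores
        m2 = (csum[n] - csum[k]) / (n - k)
        ss1 = csum2[k] - k * m1 ** 2
        ss2 = (csum2[n] - csum2[k]) - (n - k) * m2 ** 2
        sp2 = (ss1 + ss2) / (n - 2)
        if sp2 <= 0:
            t_best[k] = np.inf if m2 > m1 else -np.inf
        else:
            t_best[k] = (m2 - m1) / math.sqrt(sp2 * (1.0 / k + 1.0 / (n - k)))
    counts = overlap_map(cohort, u=binarize_u).counts
    powered = mask.include & (t_best[counts] >= critical_t)
    return PowerMap(powered=powered, critical_t=float(critical_t))
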