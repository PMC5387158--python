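"""Mass-univariate voxelwise regression with permutation FWE inference.

The group model regresses each grey-matter voxel of a quantitative map on a
subject-level design whose predictor of interest is metacognitive ability
(type-II AROC), controlling for discrimination sensitivity d', mean
confidence, criterion c, the variance-induced confidence bias, the staircase
mean-signal difference, age, gender and total intracranial volume.

Familywise-error control is by sign-respecting permutation inference with
Freedman-Lane handling of the nuisance covariates: the predictor of interest
is tested by permuting the reduced-model residuals, building a maxT null
(peak-level, optionally within a small-volume ROI mask of 5 mm spheres at
published coordinates) or a maximum-cluster-extent null (cluster level,
26-connectivity, one-tailed per signed contrast, cluster-forming p = 0.001 or
exploratory 0.005).  Permutation p-values use the tie-safe estimator
p = (1 + #{perm >= obs}) / (1 + n_perm).

Shaped after statsmodels: ``VoxelwiseRegression`` is the model,
:meth:`VoxelwiseRegression.fit` returns a :class:`VoxelwiseResults` carrying
the t-map and degrees of freedom, and ``VoxelwiseResults.permutation_fwe``
produces a :class:`StatResult` with peak and cluster tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps

from .maps import GridSpec, QMapCohort

DESIGN_COLUMNS = ["intercept", "aroc", "d_prime", "mean_confidence",
                  "criterion", "variance_bias_beta",
                  "staircase_mean_signal_diff", "age", "gender", "tiv"]

#: z-scored for conditioning; AROC stays on its native scale (t is
#: scale-invariant, the slope keeps its per-AROC-unit interpretation)
_SCALED = ["d_prime", "mean_confidence", "criterion", "variance_bias_beta",
           "staircase_mean_signal_diff", "age", "tiv"]

_SUMMARY_ALIASES = {
    "aroc": "aroc_avg", "d_prime": "d_prime_avg",
    "mean_confidence": "confidence_100_avg", "criterion": "criterion_avg",
    "variance_bias_beta": "bias_variance",
}

#: published VOI sphere centers (MNI mm): aPFC, dorsolateral PFC, precuneus
DEFAULT_VOI_CENTERS = {
    "L aPFC a": (-20, 53, 12), "L aPFC b": (-12, 54, 16),
    "R aPFC a": (24, 65, 18), "R aPFC b": (33, 50, 9),
    "R aPFC c": (32, 50, 7), "R DLPFC": (36, 39, 21),
    "Precuneus a": (6, -57, 18), "Precuneus b": (8, -64, 24),
}

_CONN26 = np.ones((3, 3, 3), dtype=bool)


def build_design(subject_summaries: pd.DataFrame) -> pd.DataFrame:
    """Assemble and scale the subject-level design matrix.

    Accepts either design-native column names or the summary-table names
    produced by ``summarise_cohort``.  Continuous covariates are z-scored,
    gender is mean-centred, AROC is left on its native scale.  Constant
    columns are dropped with a warning; remaining rank deficiency raises,
    naming the collinear columns.
    """
    df = subject_summaries
    X = pd.DataFrame(index=df.index)
    X["intercept"] = 1.0
    for col in DESIGN_COLUMNS[1:]:
        src = col if col in df.columns else _SUMMARY_ALIASES.get(col)
        if src is None or src not in df.columns:
            raise ValueError(f"summary table lacks covariate {col!r}")
        X[col] = df[src].astype(float)
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"missing covariate values in columns {bad}")
    for col in list(X.columns):
        if col == "intercept":
            continue
        v = X[col]
        if v.std(ddof=0) == 0:
            warnings.warn(f"dropping constant design column {col!r}",
                          stacklevel=2)
            X = X.drop(columns=col)
            continue
        if col in _SCALED:
            X[col] = (v - v.mean()) / v.std(ddof=0)
        elif col == "gender":
            X[col] = v - v.mean()
    A = X.to_numpy()
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # identify the offending columns via pivoted QR
        from scipy.linalg import qr
        _, R, piv = qr(A, pivoting=True)
        bad = [X.columns[p] for p in piv[rank:]]
        raise ValueError(f"design matrix is rank deficient; collinear "
                         f"columns: {bad}")
    return X


def _t_stats(E, Zq_E, xt, xx, df):
    """t for the partialled predictor given reduced-model residual data."""
    G = E - Zq_E
    num = xt @ G
    sse = np.maximum((G * G).sum(axis=0) - num ** 2 / xx, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / np.sqrt(xx * sse / df)
    return np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf)


class VoxelwiseRegression:
    """Voxelwise OLS of map values on the subject-level design.

    Parameters
    ----------
    Y : (n_subjects, n_voxels) array of in-mask map values.
    design : DataFrame from :func:`build_design` (must contain ``predictor``).
    grid : GridSpec supplying mask, shape and affine for volume output.
    predictor : design column tested voxelwise (default ``aroc``).
    """

    def __init__(self, Y, design: pd.DataFrame, grid: GridSpec,
                 predictor: str = "aroc", map_type: str | None = None):
        Y = np.asarray(Y, dtype=float)
        if Y.ndim != 2 or Y.shape[0] != len(design):
            raise ValueError("Y must be (n_subjects, n_voxels) matching design")
        if Y.shape[0] <= design.shape[1]:
            raise ValueError("fewer subjects than design columns")
        if predictor not in design.columns:
            raise ValueError(f"design lacks predictor column {predictor!r}")
        self.Y = Y
        self.design = design
        self.grid = grid
        self.predictor = predictor
        self.map_type = map_type
        self.n, self.p = Y.shape[0], design.shape[1]
        self.df = self.n - self.p

        X = design.to_numpy()
        j = list(design.columns).index(predictor)
        self.x = X[:, j]
        self.Z = np.delete(X, j, axis=1)
        self._Zq = np.linalg.pinv(self.Z)
        xt = self.x - self.Z @ (self._Zq @ self.x)
        self._xt = xt
        self._xx = float(xt @ xt)
        if self._xx <= 0:
            raise ValueError(f"predictor {predictor!r} lies in the span of "
                             "the nuisance columns")

    @classmethod
    def from_cohort(cls, cohort: QMapCohort, design: pd.DataFrame,
                    map_type: str) -> "VoxelwiseRegression":
        return cls(cohort.masked(map_type), design, cohort.grid,
                   map_type=map_type)

    def fit(self) -> "VoxelwiseResults":
        E = self.Y - self.Z @ (self._Zq @ self.Y)
        t = _t_stats(E, 0.0, self._xt, self._xx, self.df)
        beta = (self._xt @ E) / self._xx
        return VoxelwiseResults(self, t, beta)


class VoxelwiseResults:
    """Fitted voxelwise model: t and slope maps plus permutation inference."""

    def __init__(self, model: VoxelwiseRegression, t: np.ndarray,
                 beta: np.ndarray):
        self.model = model
        self.t = t          # positive-contrast t per in-mask voxel
        self.beta = beta    # predictor slope per in-mask voxel
        self.df = model.df

    def contrast_t(self, contrast: str = "pos") -> np.ndarray:
        if contrast not in ("pos", "neg"):
            raise ValueError("contrast must be 'pos' or 'neg'")
        return self.t if contrast == "pos" else -self.t

    def t_volume(self, contrast: str = "pos") -> np.ndarray:
        vol = np.full(self.model.grid.shape, np.nan)
        vol[self.model.grid.gm_mask] = self.contrast_t(contrast)
        return vol

    def permutation_fwe(self, mode: str = "peak", contrast: str = "pos",
                        voi_mask: np.ndarray | None = None,
                        cluster_forming_p: float = 0.001,
                        n_perm: int = 500, rng=None,
                        alpha: float = 0.05, seed=None) -> "StatResult":
        """Freedman-Lane permutation FWE correction of the predictor test.

        mode='peak': maxT null over the (optionally VOI-restricted) mask.
        mode='cluster': max-cluster-extent null at the cluster-forming
        threshold, 26-connectivity, one-tailed for the signed contrast.
        """
        if mode not in ("peak", "cluster"):
            raise ValueError("mode must be 'peak' or 'cluster'")
        if rng is None:
            rng = np.random.default_rng(seed)
        if n_perm < int(np.ceil(1.0 / alpha)) - 1:
            warnings.warn(f"{n_perm} permutations cannot resolve "
                          f"alpha={alpha}", stacklevel=2)
        m = self.model
        gm = m.grid.gm_mask
        if voi_mask is not None:
            if voi_mask.shape != gm.shape:
                raise ValueError("voi_mask shape does not match grid")
            sel = voi_mask[gm]
            if not sel.any():
                raise ValueError("empty mask: VOI does not intersect grey matter")
        else:
            sel = np.ones(gm.sum(), dtype=bool)

        sign = 1.0 if contrast == "pos" else -1.0
        t_obs = sign * self.t
        E = m.Y - m.Z @ (m._Zq @ m.Y)     # reduced-model residuals
        t_thr = sps.t.isf(cluster_forming_p, m.df)

        def _t_perm(perm):
            Ep = E[perm]
            return sign * _t_stats(Ep, m.Z @ (m._Zq @ Ep), m._xt, m._xx, m.df)

        def _clusters(tv):
            """Label supra-threshold clusters; returns (labels, sizes, stats)
            where stats = extent + mass/(1+mass) orders clusters by extent
            with exact-extent ties broken continuously by cluster mass (the
            integer extent null is heavily tied, which would make the
            rank-based p conservative)."""
            vol = np.zeros(gm.shape)
            vol[gm] = np.where(sel, tv, 0.0)
            labels, nlab = ndimage.label(vol > t_thr, structure=_CONN26)
            if nlab == 0:
                return labels, np.array([], dtype=int), np.array([])
            idx = np.arange(1, nlab + 1)
            sizes = np.bincount(labels.ravel())[1:]
            mass = ndimage.sum_labels(vol - t_thr, labels, idx)
            stats = sizes + mass / (1.0 + mass)
            return labels, sizes, stats

        max_t_null = np.empty(n_perm)
        max_ext_null = np.empty(n_perm)
        null_cluster_sizes = []
        for jp in range(n_perm):
            tp = _t_perm(rng.permutation(m.n))
            max_t_null[jp] = tp[sel].max()
            if mode == "cluster":
                _, sizes, stats = _clusters(tp)
                max_ext_null[jp] = stats.max() if stats.size else 0.0
                null_cluster_sizes.append(sizes)

        settings = dict(mode=mode, contrast=contrast, n_permutations=n_perm,
                        cluster_forming_p=cluster_forming_p, alpha=alpha,
                        seed=seed, df=m.df)
        peaks = self._peak_table(t_obs, sel, max_t_null, n_perm)
        if mode == "cluster":
            clusters = self._cluster_table(t_obs, _clusters, max_ext_null,
                                           np.concatenate(null_cluster_sizes)
                                           if null_cluster_sizes else
                                           np.array([], dtype=int), n_perm)
        else:
            clusters = pd.DataFrame(columns=["k", "x", "y", "z", "t_peak",
                                             "p_fwe_cluster", "p_uncorrected"])
        tvol = np.full(gm.shape, np.nan)
        tvol[gm] = t_obs
        return StatResult(t_map=tvol, contrast=contrast, mode=mode,
                          peaks=peaks, clusters=clusters, settings=settings,
                          map_type=m.map_type, grid=m.grid)

    def _peak_table(self, t_obs, sel, max_t_null, n_perm):
        gm = self.model.grid.gm_mask
        vol = np.full(gm.shape, -np.inf)
        flat = np.where(sel, t_obs, -np.inf)
        vol[gm] = flat
        local_max = (vol == ndimage.maximum_filter(vol, size=3)) & np.isfinite(vol)
        ijk = np.argwhere(local_max)
        rows = []
        for v in ijk:
            tv = vol[tuple(v)]
            p_fwe = (1 + np.sum(max_t_null >= tv)) / (1 + n_perm)
            xyz = self.model.grid.voxel_to_world(v)
            rows.append(dict(x=float(xyz[0]), y=float(xyz[1]),
                             z=float(xyz[2]), t=float(tv),
                             p_fwe_peak=float(p_fwe),
                             p_uncorrected=float(sps.t.sf(tv, self.df))))
        peaks = pd.DataFrame(rows, columns=["x", "y", "z", "t", "p_fwe_peak",
                                            "p_uncorrected"])
        return peaks.sort_values("t", ascending=False).head(20) \
                    .reset_index(drop=True)

    def _cluster_table(self, t_obs, _clusters, max_ext_null, pooled_null,
                       n_perm):
        labels, sizes, stats = _clusters(t_obs)
        rows = []
        for lab in range(1, sizes.size + 1):
            k = int(sizes[lab - 1])
            inside = labels == lab
            tvals = np.where(inside, np.nan_to_num(
                self._as_volume(t_obs), nan=-np.inf), -np.inf)
            peak = np.unravel_index(np.argmax(tvals), tvals.shape)
            xyz = self.model.grid.voxel_to_world(np.array(peak))
            p_fwe = (1 + np.sum(max_ext_null >= stats[lab - 1])) / (1 + n_perm)
            p_unc = ((1 + np.sum(pooled_null >= k)) / (1 + pooled_null.size)
                     if pooled_null.size else 1.0 / (1 + n_perm))
            rows.append(dict(k=k, x=float(xyz[0]), y=float(xyz[1]),
                             z=float(xyz[2]), t_peak=float(tvals[peak]),
                             p_fwe_cluster=float(p_fwe),
                             p_uncorrected=float(p_unc)))
        cols = ["k", "x", "y", "z", "t_peak", "p_fwe_cluster", "p_uncorrected"]
        df = pd.DataFrame(rows, columns=cols)
        return df.sort_values("k", ascending=False).reset_index(drop=True)

    def _as_volume(self, flat):
        vol = np.full(self.model.grid.shape, np.nan)
        vol[self.model.grid.gm_mask] = flat
        return vol

    def summary(self) -> str:
        lines = [
            "Voxelwise regression results",
            "=" * 32,
            f"map type:        {self.model.map_type or 'unspecified'}",
            f"predictor:       {self.model.predictor}",
            f"subjects:        {self.model.n}",
            f"design columns:  {self.model.p}",
            f"df:              {self.df}",
            f"in-mask voxels:  {self.t.size}",
            f"max t (pos):     {self.t.max():.3f}",
            f"max t (neg):     {(-self.t).max():.3f}",
        ]
        return "\n".join(lines)


@dataclass
class StatResult:
    """Permutation-corrected inference for one map, contrast and mode."""

    t_map: np.ndarray
    contrast: str
    mode: str
    peaks: pd.DataFrame
    clusters: pd.DataFrame
    settings: dict
    map_type: str | None = None
    grid: GridSpec | None = None

    def __post_init__(self):
        if len(self.clusters) and (self.clusters["k"] < 1).any():
            raise ValueError("cluster extents must be >= 1")
        for frame, col in ((self.peaks, "p_fwe_peak"),
                           (self.clusters, "p_fwe_cluster")):
            if len(frame) and not frame[col].between(0, 1).all():
                raise ValueError(f"{col} outside [0, 1]")


def fit_voxelwise(cohort: QMapCohort, design: pd.DataFrame, map_type: str,
                  contrast: str = "pos") -> np.ndarray:
    """t-statistic volume of the AROC contrast for one map type."""
    res = VoxelwiseRegression.from_cohort(cohort, design, map_type).fit()
    return res.t_volume(contrast)


def make_voi_mask(grid: GridSpec, centers: dict | list | None = None,
                  radius_mm: float = 5.0, restrict_to_gm: bool = True):
    """Union of spherical VOIs; returns (mask, provenance table).

    A voxel joins a sphere when its world-space center lies within
    ``radius_mm`` of the sphere center; each sphere always contains the voxel
    nearest its center (so radius 0 keeps exactly the center voxels).  The
    union is intersected with the grey-matter analysis mask by default.
    """
    if centers is None:
        centers = DEFAULT_VOI_CENTERS
    if not isinstance(centers, dict):
        centers = {f"voi_{i}": tuple(c) for i, c in enumerate(centers)}
    xs, ys, zs = grid.world_grids()
    mask = np.zeros(grid.shape, dtype=bool)
    rows = []
    for name, c in centers.items():
        ijk = grid.world_to_voxel(c)
        if not grid.contains_voxel(ijk):
            raise ValueError(f"VOI center {name} at {c} lies outside the grid")
        d2 = (xs - c[0]) ** 2 + (ys - c[1]) ** 2 + (zs - c[2]) ** 2
        sphere = d2 <= radius_mm ** 2
        sphere[tuple(ijk)] = True
        mask |= sphere
        rows.append(dict(name=name, x=c[0], y=c[1], z=c[2],
                         n_voxels=int(sphere.sum())))
    if restrict_to_gm:
        mask &= grid.gm_mask
    return mask, pd.DataFrame(rows)


REPORT_COLUMNS = ["map", "contrast", "mode", "k", "p_fwe", "p_uncorrected",
                  "t", "x", "y", "z"]


def report_tables(results: list[StatResult], path=None) -> pd.DataFrame:
    """Flatten StatResults into one report table (one row per peak/cluster)."""
    rows = []
    for r in results:
        if r.mode == "cluster":
            for _, c in r.clusters.iterrows():
                rows.append(dict(map=r.map_type, contrast=r.contrast,
                                 mode=r.mode, k=int(c["k"]),
                                 p_fwe=c["p_fwe_cluster"],
                                 p_uncorrected=c["p_uncorrected"],
                                 t=c["t_peak"], x=c["x"], y=c["y"], z=c["z"]))
        else:
            for _, pk in r.peaks.iterrows():
                rows.append(dict(map=r.map_type, contrast=r.contrast,
                                 mode=r.mode, k=1, p_fwe=pk["p_fwe_peak"],
                                 p_uncorrected=pk["p_uncorrected"],
                                 t=pk["t"], x=pk["x"], y=pk["y"], z=pk["z"]))
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if path is not None:
        df.to_csv(path, index=False)
    return df
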