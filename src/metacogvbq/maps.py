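"""Synthetic per-subject quantitative brain maps with planted effects.

Emulates the statistical structure a voxel-based quantification (VBQ) group
regression assumes: each subject contributes grey-matter maps of three
quantitative MRI parameters — MT saturation (percent units, myelin-sensitive),
R1 (1/s, myelin/iron-sensitive) and R2* (1/s, iron-sensitive) — on a shared
MNI-like grid.  A subject's map is

    baseline + sum_sites slope * (predictor - mean) * spatial_kernel
             + nuisance fields (age, gender, TIV)
             + smooth Gaussian noise (default 4 mm FWHM)

where the planted sites mirror the regions in which metacognitive ability
(type-II AROC) has been related to grey-matter microstructure: right anterior
prefrontal cortex (MT+, R1+), left hippocampus (MT-), precuneus (R2*+),
primary visual cortex (R2*-) and left middle temporal gyrus (R2*+).

No MRI physics is simulated; the generator exists so the voxelwise regression
and its permutation inference can be validated end to end against known
ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import nibabel as nib
from scipy import ndimage

MAP_TYPES = ("MT", "R1", "R2star")

#: plausible grey-matter baselines (MT in percent units, R1 and R2* in 1/s)
BASELINES = {"MT": 0.9, "R1": 0.6, "R2star": 16.0}

#: between-subject noise SD after smoothing, per map (same units as baseline)
NOISE_SD = {"MT": 0.045, "R1": 0.03, "R2star": 1.0}

#: nuisance slopes per map: (per year of age, per gender code, per ml TIV)
NUISANCE_SLOPES = {
    "MT": {"age": -0.0030, "gender": 0.010, "tiv": 1.0e-5},
    "R1": {"age": -0.0015, "gender": 0.006, "tiv": 0.6e-5},
    "R2star": {"age": 0.050, "gender": 0.20, "tiv": 2.0e-4},
}

# MNI-like brain envelope: ellipsoid centred near the AC, sized so every
# published coordinate used by the analysis falls well inside grey matter.
_ELLIPSOID_CENTER = np.array([0.0, -16.0, 6.0])
_ELLIPSOID_SEMI = np.array([60.0, 92.0, 55.0])


@dataclass
class GridSpec:
    """Analysis grid: shape, voxel-to-world affine and grey-matter mask."""

    shape: tuple[int, int, int]
    affine: np.ndarray
    gm_mask: np.ndarray

    def __post_init__(self):
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        self.gm_mask = np.asarray(self.gm_mask, dtype=bool)
        if self.gm_mask.shape != tuple(self.shape):
            raise ValueError("gm_mask shape does not match grid shape")

    @property
    def voxel_size_mm(self) -> float:
        return float(np.abs(self.affine[0, 0]))

    def world_to_voxel(self, xyz) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        ijk = (inv[:3, :3] @ xyz.T).T + inv[:3, 3]
        return np.rint(ijk).astype(int).squeeze()

    def voxel_to_world(self, ijk) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ((self.affine[:3, :3] @ ijk.T).T + self.affine[:3, 3]).squeeze()

    def contains_voxel(self, ijk) -> bool:
        ijk = np.atleast_1d(ijk)
        return bool(np.all(ijk >= 0) and np.all(ijk < np.array(self.shape)))

    def world_grids(self):
        """World coordinates of every voxel center, one 3D array per axis."""
        idx = np.indices(self.shape, dtype=float)
        flat = idx.reshape(3, -1).T
        world = (self.affine[:3, :3] @ flat.T).T + self.affine[:3, 3]
        return [world[:, a].reshape(self.shape) for a in range(3)]

    @classmethod
    def default(cls, voxel_size_mm: float = 2.0, margin_mm: float = 4.0):
        """MNI-like grid whose ellipsoidal GM mask contains the printed
        coordinates; supports voxel sizes down to 0.8 mm."""
        if voxel_size_mm < 0.8:
            raise ValueError("voxel_size_mm below the supported 0.8 mm floor")
        lo = _ELLIPSOID_CENTER - _ELLIPSOID_SEMI - margin_mm
        hi = _ELLIPSOID_CENTER + _ELLIPSOID_SEMI + margin_mm
        shape = tuple(int(np.ceil((hi[a] - lo[a]) / voxel_size_mm)) + 1
                      for a in range(3))
        affine = np.diag([voxel_size_mm] * 3 + [1.0])
        affine[:3, 3] = lo
        grid = cls(shape, affine, np.ones(shape, dtype=bool))
        xs, ys, zs = grid.world_grids()
        u = (((xs - _ELLIPSOID_CENTER[0]) / _ELLIPSOID_SEMI[0]) ** 2
             + ((ys - _ELLIPSOID_CENTER[1]) / _ELLIPSOID_SEMI[1]) ** 2
             + ((zs - _ELLIPSOID_CENTER[2]) / _ELLIPSOID_SEMI[2]) ** 2)
        grid.gm_mask = u <= 1.0
        return grid


@dataclass
class EffectSite:
    """One planted voxelwise linear effect of a behavioural predictor."""

    world_xyz: tuple[float, float, float]
    map: str                       # MT | R1 | R2star
    predictor: str                 # column of the subject summary table
    slope: float                   # map units per predictor unit; sign = direction
    spatial_extent_mm: float = 8.0

    def __post_init__(self):
        if self.map not in MAP_TYPES:
            raise ValueError(f"unknown map type {self.map!r}")


def default_effect_sites() -> list[EffectSite]:
    """Planted AROC effects at the canonical coordinates.

    Slopes are scaled so that one between-subject SD of AROC (~0.06) moves
    the map by about one noise SD at the peak, emulating peak t-values in the
    4-6 range for a ~48-subject cohort.
    """
    s = {"MT": NOISE_SD["MT"] / 0.06, "R1": NOISE_SD["R1"] / 0.06,
         "R2star": NOISE_SD["R2star"] / 0.06}
    return [
        EffectSite((37, 41, 22), "MT", "aroc", +s["MT"]),       # R aPFC
        EffectSite((37, 42, 22), "R1", "aroc", +s["R1"]),       # R aPFC
        EffectSite((-31, -25, -14), "MT", "aroc", -s["MT"]),    # L hippocampus
        EffectSite((9, -64, 24), "R2star", "aroc", +s["R2star"]),   # precuneus
        EffectSite((1, -69, 11), "R2star", "aroc", -s["R2star"]),   # V1
        EffectSite((-51, -48, 2), "R2star", "aroc", +s["R2star"]),  # L MTG
    ]


@dataclass
class QMapCohort:
    """Per-subject quantitative map volumes on a shared grid."""

    subject_ids: list
    data: dict                     # map type -> (n_subjects, *shape) array
    grid: GridSpec
    noise_fwhm_mm: float
    truth: list[EffectSite] = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def masked(self, map_type: str) -> np.ndarray:
        """(n_subjects, n_mask_voxels) view of one map type."""
        return self.data[map_type][:, self.grid.gm_mask]


def smooth_noise_volume(shape, fwhm_mm, voxel_size_mm, rng, sd=1.0):
    """Gaussian white noise smoothed to ``fwhm_mm`` and rescaled to SD ``sd``.

    Smoothing a white field with a Gaussian kernel of FWHM w yields a field
    whose resel-based smoothness equals w, which is what the empirical FWHM
    estimator measures.
    """
    vol = rng.standard_normal(shape)
    if fwhm_mm > 0:
        sigma_vox = fwhm_mm / (np.sqrt(8 * np.log(2)) * voxel_size_mm)
        vol = ndimage.gaussian_filter(vol, sigma_vox, mode="constant")
        vol /= vol.std()
    return vol * sd


def estimate_fwhm(volume, mask, voxel_size_mm) -> float:
    """Empirical smoothness (mm FWHM) of a noise field from gradient variance.

    Uses the lag-1 autocorrelation of in-mask first differences per axis:
    for a Gaussian-kernel-smoothed white field the autocorrelation at lag d
    is exp(-d^2 / (4 sigma^2)) with FWHM = sqrt(8 ln 2) sigma.
    """
    v = volume[mask].var()
    est = []
    for axis in range(3):
        inner = mask & np.roll(mask, -1, axis=axis)
        inner[tuple(slice(None) if a != axis else slice(-1, None)
                    for a in range(3))] = False
        d = (np.roll(volume, -1, axis=axis) - volume)[inner]
        rho = 1.0 - d.var() / (2.0 * v)
        if rho <= 0:
            continue
        sigma = np.sqrt(-voxel_size_mm ** 2 / (4.0 * np.log(rho)))
        est.append(np.sqrt(8 * np.log(2)) * sigma)
    if not est:
        raise ValueError("field rougher than the voxel grid; FWHM inestimable")
    return float(np.mean(est))


def generate_cohort_maps(subject_summaries: pd.DataFrame,
                         sites: list[EffectSite] | None = None,
                         grid: GridSpec | None = None,
                         noise_sd: dict | None = None,
                         noise_fwhm_mm: float = 4.0,
                         rng=None,
                         nuisance_slopes: dict | None = None) -> QMapCohort:
    """Generate MT/R1/R2* volumes for every subject in the summary table.

    ``subject_summaries`` must contain every predictor a site references
    (default sites use ``aroc``, resolved to ``aroc_avg`` if needed) plus the
    ``age``/``gender``/``tiv`` nuisance covariates.  Predictors are
    mean-centred before planting, so the baseline is the cohort-mean map.
    """
    if rng is None:
        rng = np.random.default_rng()
    if len(subject_summaries) < 10:
        raise ValueError("need >= 10 subjects for a meaningful voxelwise regression")
    sites = default_effect_sites() if sites is None else sites
    grid = grid or GridSpec.default()
    noise_sd = dict(NOISE_SD if noise_sd is None else noise_sd)
    nuisance = NUISANCE_SLOPES if nuisance_slopes is None else nuisance_slopes

    def _pred(name):
        if name in subject_summaries.columns:
            return subject_summaries[name].to_numpy(dtype=float)
        alt = f"{name}_avg"
        if alt in subject_summaries.columns:
            return subject_summaries[alt].to_numpy(dtype=float)
        raise ValueError(f"predictor {name!r} missing from the summary table")

    n = len(subject_summaries)
    xs, ys, zs = grid.world_grids()
    effect_fields = {m: np.zeros((n,) + tuple(grid.shape)) for m in MAP_TYPES}
    for site in sites:
        ijk = grid.world_to_voxel(site.world_xyz)
        if not grid.contains_voxel(ijk) or not grid.gm_mask[tuple(ijk)]:
            raise ValueError(f"effect site {site.world_xyz} is outside the "
                             "grey-matter mask")
        p = _pred(site.predictor)
        p = p - p.mean()
        sig = site.spatial_extent_mm / 2.0
        d2 = ((xs - site.world_xyz[0]) ** 2 + (ys - site.world_xyz[1]) ** 2
              + (zs - site.world_xyz[2]) ** 2)
        kernel = np.exp(-d2 / (2.0 * sig ** 2))
        kernel[d2 > (3.0 * sig) ** 2] = 0.0
        effect_fields[site.map] += site.slope * p[:, None, None, None] * kernel

    data = {}
    for m in MAP_TYPES:
        vols = np.zeros((n,) + tuple(grid.shape))
        base = BASELINES[m]
        for i in range(n):
            vol = np.full(grid.shape, base)
            for cov, slope in nuisance[m].items():
                c = _pred(cov)
                vol += slope * (c[i] - c.mean())
            vol += effect_fields[m][i]
            if noise_sd.get(m, 0) > 0:
                vol += smooth_noise_volume(grid.shape, noise_fwhm_mm,
                                           grid.voxel_size_mm, rng,
                                           sd=noise_sd[m])
            vol = np.maximum(vol, 1e-3 * base)   # map values stay positive
            vol[~grid.gm_mask] = 0.0
            vols[i] = vol
        data[m] = vols
    ids = list(subject_summaries.index)
    return QMapCohort(ids, data, grid, noise_fwhm_mm, list(sites))


def _site_to_dict(s: EffectSite) -> dict:
    return dict(world_xyz=list(map(float, s.world_xyz)), map=s.map,
                predictor=s.predictor, slope=float(s.slope),
                spatial_extent_mm=float(s.spatial_extent_mm))


def write_cohort(cohort: QMapCohort, out_dir) -> dict:
    """Write one NIfTI per subject per map plus mask and truth manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    for m in MAP_TYPES:
        for i, sid in enumerate(cohort.subject_ids):
            path = out / f"sub-{sid:03d}_{m}.nii" if isinstance(sid, (int, np.integer)) \
                else out / f"sub-{sid}_{m}.nii"
            img = nib.Nifti1Image(cohort.data[m][i].astype(np.float32),
                                  cohort.grid.affine)
            nib.save(img, path)
            files.setdefault(m, []).append(path.name)
    mask_img = nib.Nifti1Image(cohort.grid.gm_mask.astype(np.uint8),
                               cohort.grid.affine)
    nib.save(mask_img, out / "gm_mask.nii")
    manifest = dict(subject_ids=[int(s) if isinstance(s, (int, np.integer))
                                 else s for s in cohort.subject_ids],
                    files=files, noise_fwhm_mm=cohort.noise_fwhm_mm,
                    truth=[_site_to_dict(s) for s in cohort.truth])
    (out / "cohort.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def read_cohort(in_dir) -> QMapCohort:
    """Round-trip counterpart of :func:`write_cohort`; validates the grid."""
    src = Path(in_dir)
    manifest = json.loads((src / "cohort.json").read_text())
    mask_img = nib.load(src / "gm_mask.nii")
    affine = mask_img.affine
    mask = np.asarray(mask_img.dataobj).astype(bool)
    grid = GridSpec(mask.shape, affine, mask)
    data = {}
    for m, names in manifest["files"].items():
        vols = []
        for name in names:
            img = nib.load(src / name)
            if img.shape != mask.shape or not np.allclose(img.affine, affine):
                raise ValueError(f"grid mismatch in {name}: all subjects must "
                                 "share shape and affine")
            vols.append(np.asarray(img.dataobj, dtype=np.float64))
        data[m] = np.stack(vols)
    truth = [EffectSite(tuple(t["world_xyz"]), t["map"], t["predictor"],
                        t["slope"], t["spatial_extent_mm"])
             for t in manifest["truth"]]
    return QMapCohort(manifest["subject_ids"], data, grid,
                      manifest["noise_fwhm_mm"], truth)
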