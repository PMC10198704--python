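"""Activation likelihood estimation (ALE) meta-analysis of reported coordinates.

Each study contributes a modelled-activation (MA) map: a 3-D Gaussian is
centred on every reported focus, its width set by a two-component spatial
uncertainty model (a fixed between-template term plus a between-subject term
shrinking as 1/sqrt(n)); within a study the MA value at a voxel is the MAXIMUM
over that study's focus kernels, so duplicated foci do not inflate evidence.
Across studies the ALE statistic is the probabilistic union
ALE = 1 - prod(1 - MA_i). Inference relocates every study's foci uniformly at
random inside the analysis mask, pools the resulting null ALE values across
voxels (valid because relocation makes voxels exchangeable), forms clusters at
an uncorrected voxel threshold, and corrects them with the permutation
distribution of the maximum cluster size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import BinaryMask, ScalarVolume, VolumeGrid, connected_components
from .inference import PermutationScheme

__all__ = [
    "FocusSet",
    "ALECluster",
    "ALEResult",
    "kernel_fwhm",
    "study_ma_map",
    "ale_map",
    "ale_inference",
    "read_focus_table",
    "write_focus_table",
]

#: Empirical Euclidean-distance uncertainties (mm) of the published ALE model:
#: between-template and between-subject displacement of reported foci. These
#: are cited constants of the standard tool, not quantities fitted here.
TEMPLATE_UNCERTAINTY_ED_MM = 5.7
SUBJECT_UNCERTAINTY_ED_MM = 11.6

_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


def _euclidean_distance_to_fwhm(ed_mm: float) -> float:
    """Convert a mean 3-D Euclidean displacement to the per-axis Gaussian FWHM
    (ED = 2*sigma*sqrt(2/pi) for a 3-D isotropic Gaussian)."""
    sigma = ed_mm / (2.0 * math.sqrt(2.0 / math.pi))
    return sigma * _FWHM_PER_SIGMA


def kernel_fwhm(n_subjects: int) -> float:
    """FWHM (mm) of the per-focus Gaussian for a study of ``n_subjects``.

    Strictly decreasing in n; the n -> infinity limit is the template-only
    component.
    """
    if n_subjects < 1:
        raise ValueError(f"n_subjects must be >= 1, got {n_subjects}")
    f_t = _euclidean_distance_to_fwhm(TEMPLATE_UNCERTAINTY_ED_MM)
    f_s = _euclidean_distance_to_fwhm(SUBJECT_UNCERTAINTY_ED_MM)
    return math.sqrt(f_t**2 + f_s**2 / n_subjects)


@dataclass
class FocusSet:
    """One study's reported foci (world mm), sample size and the direction of
    the underlying volume difference (higher|lower volume in patients)."""

    study_id: str
    foci: np.ndarray  # (k, 3) world mm
    n_subjects: int
    direction: str = "lower"

    def __post_init__(self) -> None:
        foci = np.atleast_2d(np.asarray(self.foci, dtype=float))
        if foci.shape[0] < 1 or foci.shape[1] != 3:
            raise ValueError(f"{self.study_id}: foci must be a (k, 3) array")
        if self.n_subjects < 1:
            raise ValueError(f"{self.study_id}: n_subjects must be >= 1")
        if self.direction not in ("higher", "lower"):
            raise ValueError(
                f"{self.study_id}: direction must be 'higher' or 'lower', "
                f"got {self.direction!r}"
            )
        self.foci = foci


@dataclass
class ALECluster:
    cog_mm: tuple[float, float, float]  # ALE-weighted centre of gravity
    peak_ale: float
    cog_ale: float  # ALE at the voxel nearest the centre of gravity
    size_voxels: int
    fwe_p: float


@dataclass
class ALEResult:
    ale: ScalarVolume
    voxel_p: ScalarVolume
    clusters: list[ALECluster]
    ale_cluster_threshold: float  # ALE value realising the cluster-forming p
    scheme: PermutationScheme

    def significant_clusters(self, alpha: float = 0.05) -> list[ALECluster]:
        return [c for c in self.clusters if c.fwe_p < alpha]


# ---------------------------------------------------------------------------
# kernels and MA / ALE maps
# ---------------------------------------------------------------------------

def _gaussian_kernel(fwhm_mm: float, voxel_size_mm: np.ndarray,
                     truncate_sigma: float = 3.5) -> np.ndarray:
    """Unit-mass 3-D Gaussian sampled on the voxel lattice (probability of the
    'true' location falling in each voxel)."""
    sigma_mm = fwhm_mm / _FWHM_PER_SIGMA
    half = np.ceil(truncate_sigma * sigma_mm / voxel_size_mm).astype(int)
    axes = [np.arange(-h, h + 1) * v for h, v in zip(half, voxel_size_mm)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    d2 = xx**2 + yy**2 + zz**2
    k = np.exp(-d2 / (2.0 * sigma_mm**2))
    return k / k.sum()


def _paste_max(target: np.ndarray, kernel: np.ndarray, center_idx) -> None:
    """target[window] = max(target[window], kernel) with edge clipping."""
    half = (np.asarray(kernel.shape) - 1) // 2
    lo = np.asarray(center_idx) - half
    hi = lo + kernel.shape
    klo = np.maximum(-lo, 0)
    khi = np.asarray(kernel.shape) - np.maximum(hi - target.shape, 0)
    lo_c = np.maximum(lo, 0)
    hi_c = np.minimum(hi, target.shape)
    view = target[lo_c[0]:hi_c[0], lo_c[1]:hi_c[1], lo_c[2]:hi_c[2]]
    np.maximum(view, kernel[klo[0]:khi[0], klo[1]:khi[1], klo[2]:khi[2]], out=view)


def _ma_array(foci_idx: np.ndarray, kernel: np.ndarray, dims) -> np.ndarray:
    ma = np.zeros(dims, dtype=float)
    for idx in foci_idx:
        _paste_max(ma, kernel, idx)
    return ma


def study_ma_map(fs: FocusSet, grid: VolumeGrid) -> ScalarVolume:
    """Modelled-activation map of a study: max over its focus kernels."""
    kernel = _gaussian_kernel(kernel_fwhm(fs.n_subjects), grid.voxel_size_mm)
    foci_idx = np.array([grid.world_to_voxel(f) for f in fs.foci])
    return ScalarVolume(grid, _ma_array(foci_idx, kernel, grid.dims))


def ale_map(ma_maps: list[ScalarVolume]) -> ScalarVolume:
    """ALE(v) = 1 - prod_i (1 - MA_i(v)); union of study probabilities.

    The factors are multiplied in a per-voxel canonical (sorted) order, so the
    result is bit-identical under any permutation of the studies despite
    floating-point non-associativity; a single study returns its MA map
    verbatim.
    """
    if not ma_maps:
        raise ValueError("ale_map requires at least one MA map")
    grid = ma_maps[0].grid
    stack = []
    for ma in ma_maps:
        grid.require_matches(ma.grid, "MA maps")
        vals = np.asarray(ma.values, dtype=float)
        if vals.min() < 0 or vals.max() > 1:
            raise ValueError("MA values must lie in [0, 1]")
        stack.append(vals)
    if len(stack) == 1:
        return ScalarVolume(grid, stack[0].copy())
    one_minus = np.sort(1.0 - np.stack(stack), axis=0)
    return ScalarVolume(grid, 1.0 - np.multiply.reduce(one_minus, axis=0))


# ---------------------------------------------------------------------------
# permutation inference
# ---------------------------------------------------------------------------

def ale_inference(studies: list[FocusSet], mask: BinaryMask,
                  scheme: PermutationScheme | None = None,
                  cluster_forming_p: float = 0.001,
                  cluster_alpha: float = 0.05,
                  connectivity: int = 26) -> ALEResult:
    """Full ALE analysis: observed ALE, pooled permutation voxel p-values,
    clusters at ``cluster_forming_p`` and cluster-level FWE p-values.

    The null relocates each study's foci uniformly at random within the mask
    (same focus counts and sample sizes) and recomputes ALE; voxel p-values
    come from the null ALE values pooled across voxels and permutations, and
    cluster FWE p-values from the null distribution of the maximum cluster
    size at the same ALE cutoff. Deterministic given ``scheme.rng_seed``.
    """
    if len(studies) < 2:
        raise ValueError("need >= 2 studies for a meaningful permutation null")
    scheme = scheme or PermutationScheme()
    grid = mask.grid
    in_mask = mask.flat_indices
    mask_idx = np.argwhere(mask.membership)  # (V, 3) voxel indices
    rng = np.random.default_rng(scheme.rng_seed)

    kernels = [_gaussian_kernel(kernel_fwhm(fs.n_subjects), grid.voxel_size_mm)
               for fs in studies]
    observed = ale_map([study_ma_map(fs, grid) for fs in studies])
    obs_in_mask = observed.values.ravel()[in_mask]

    n_perm, n_vox = scheme.n_perm, in_mask.size
    null_maps = np.empty((n_perm, n_vox), dtype=np.float32)
    for p in range(n_perm):
        one_minus = np.ones(grid.dims, dtype=float)
        for fs, kernel in zip(studies, kernels):
            loc = mask_idx[rng.integers(0, mask_idx.shape[0], size=fs.foci.shape[0])]
            one_minus *= 1.0 - _ma_array(loc, kernel, grid.dims)
        null_maps[p] = (1.0 - one_minus).ravel()[in_mask]

    null_sorted = np.sort(null_maps, axis=None)
    n_null = null_sorted.size
    # pooled empirical p with add-one correction
    count_ge = n_null - np.searchsorted(null_sorted, obs_in_mask, side="left")
    voxel_p_in_mask = (1.0 + count_ge) / (n_null + 1.0)

    voxel_p = np.ones(grid.n_voxels)
    voxel_p[in_mask] = voxel_p_in_mask
    voxel_p_vol = ScalarVolume(grid, voxel_p.reshape(grid.dims))

    # ALE cutoff realising the cluster-forming p on the pooled null: a voxel
    # passes iff fewer than k_max null values are >= its ALE.
    k_max = int(np.floor(cluster_forming_p * (n_null + 1.0) - 1.0))
    clusters: list[ALECluster] = []
    if k_max < 0:
        a_crit = float("inf")
    else:
        a_crit = float(null_sorted[n_null - k_max - 1])
        supra = np.zeros(grid.dims, dtype=bool)
        supra.ravel()[in_mask] = obs_in_mask > a_crit
        labels, sizes = connected_components(supra, connectivity)
        if sizes.size:
            null_max_size = np.zeros(n_perm, dtype=int)
            for p in range(n_perm):
                perm_supra = np.zeros(grid.dims, dtype=bool)
                perm_supra.ravel()[in_mask] = null_maps[p] > a_crit
                _, perm_sizes = connected_components(perm_supra, connectivity)
                null_max_size[p] = perm_sizes.max() if perm_sizes.size else 0
            ale_vals = np.asarray(observed.values)
            for lbl, size in enumerate(sizes, start=1):
                member = labels == lbl
                w = ale_vals[member]
                coords = grid.voxel_to_world(np.argwhere(member))
                cog = tuple(np.average(coords, axis=0, weights=w))
                fwe_p = (1.0 + int((null_max_size >= size).sum())) / (n_perm + 1.0)
                cog_idx = grid.world_to_voxel(cog)
                clusters.append(ALECluster(
                    cog_mm=cog,
                    peak_ale=float(w.max()),
                    cog_ale=float(ale_vals[cog_idx]),
                    size_voxels=int(size),
                    fwe_p=float(fwe_p),
                ))
            clusters.sort(key=lambda c: -c.size_voxels)
    return ALEResult(
        ale=observed,
        voxel_p=voxel_p_vol,
        clusters=clusters,
        ale_cluster_threshold=a_crit,
        scheme=scheme,
    )


# ---------------------------------------------------------------------------
# coordinate table I/O (shared with coordinate network mapping)
# ---------------------------------------------------------------------------

_FOCUS_COLUMNS = ["study_id", "x", "y", "z", "n_subjects", "direction"]


def read_focus_table(path) -> list[FocusSet]:
    """Read a delimited coordinate table with columns
    study_id, x, y, z, n_subjects, direction (one row per focus)."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in _FOCUS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: coordinate table is missing columns {missing}")
    studies = []
    for study_id, g in df.groupby("study_id", sort=False):
        n = g["n_subjects"].unique()
        direction = g["direction"].unique()
        if len(n) != 1 or len(direction) != 1:
            raise ValueError(
                f"{path}: study {study_id!r} has inconsistent n_subjects/direction"
            )
        studies.append(FocusSet(
            study_id=str(study_id),
            foci=g[["x", "y", "z"]].to_numpy(dtype=float),
            n_subjects=int(n[0]),
            direction=str(direction[0]),
        ))
    return studies


def write_focus_table(studies: list[FocusSet], path) -> None:
    rows = []
    for fs in studies:
        for x, y, z in fs.foci:
            rows.append({"study_id": fs.study_id, "x": x, "y": y, "z": z,
                         "n_subjects": fs.n_subjects, "direction": fs.direction})
    pd.DataFrame(rows, columns=_FOCUS_COLUMNS).to_csv(Path(path), sep="\t", index=False)
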