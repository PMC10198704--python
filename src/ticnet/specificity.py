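"""Specificity of the lesion network: two-group GLM with TFCE permutation FWE.

Voxels *sensitive* to the symptom (connected to most case lesions) may also be
connected to lesions in general. The specificity stage compares the seed
t-maps of case lesions against those of control-disorder lesions with a
voxelwise two-sample GLM, enhances the group-difference map with
threshold-free cluster enhancement (TFCE), and assigns family-wise-error
corrected p-values from the permutation distribution of the maximum TFCE
statistic under random relabelling of the two lesion groups. Restricting the
significant voxels to the sensitivity network yields the "sensitive and
specific" network.

The permutation null uses the maximum of the positive- and negative-direction
TFCE maxima in each permutation, so the reported p-values control family-wise
error over both directions jointly at the nominal level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

from .grid import BinaryMask, ScalarVolume, connected_components, intersect_masks
from .inference import PermutationScheme, TfceParams

__all__ = [
    "SpecificityResult",
    "two_sample_glm_tmap",
    "tfce",
    "permutation_fwe",
    "sensitive_and_specific",
]


@dataclass
class SpecificityResult:
    group_t: ScalarVolume
    tfce_pos: ScalarVolume
    tfce_neg: ScalarVolume
    fwe_p_pos: ScalarVolume
    fwe_p_neg: ScalarVolume
    significant_pos: BinaryMask
    significant_neg: BinaryMask
    scheme: PermutationScheme
    df: int


def _two_sample_t(case: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Vectorised pooled-variance two-sample t (cases minus controls) over the
    last axis; zero pooled variance -> t = 0."""
    n1, n2 = case.shape[0], control.shape[0]
    m1, m2 = case.mean(axis=0), control.mean(axis=0)
    ss1 = ((case - m1) ** 2).sum(axis=0)
    ss2 = ((control - m2) ** 2).sum(axis=0)
    pooled_var = (ss1 + ss2) / (n1 + n2 - 2)
    se = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    return np.divide(m1 - m2, se, out=np.zeros_like(se), where=se > 0)


def two_sample_glm_tmap(case_maps: list[ScalarVolume],
                        control_maps: list[ScalarVolume]) -> ScalarVolume:
    """Voxelwise two-sample t-map (cases minus controls), df = n1 + n2 - 2."""
    if len(case_maps) < 2 or len(control_maps) < 2:
        raise ValueError("need >= 2 maps per group")
    grid = case_maps[0].grid
    for m in case_maps + control_maps:
        grid.require_matches(m.grid, "t-maps")
    case = np.stack([np.asarray(m.values, float).ravel() for m in case_maps])
    control = np.stack([np.asarray(m.values, float).ravel() for m in control_maps])
    return ScalarVolume(grid, _two_sample_t(case, control))


def _tfce_array(stat: np.ndarray, params: TfceParams) -> np.ndarray:
    """TFCE(v) = sum_h e(h, v)^E * h^H * dh over 0 < h <= stat(v), where
    e(h, v) is the voxel count of the connected component containing v at
    threshold h. Only positive values are enhanced; run on -stat for the
    negative direction."""
    stat = np.asarray(stat, dtype=float)
    out = np.zeros_like(stat)
    peak = stat.max(initial=0.0)
    if peak <= 0:
        return out
    dh = peak / params.n_steps
    hs = dh * np.arange(1, params.n_steps + 1)
    for h in hs:
        supra = stat >= h
        labels, sizes = connected_components(supra, params.connectivity)
        if sizes.size == 0:
            break
        extent = np.zeros(sizes.size + 1)
        extent[1:] = sizes.astype(float) ** params.E
        out += extent[labels] * (h ** params.H) * dh
    return out


def tfce(stat: ScalarVolume, params: TfceParams | None = None) -> ScalarVolume:
    """Threshold-free cluster enhancement of the positive part of a map."""
    params = params or TfceParams()
    return ScalarVolume(stat.grid, _tfce_array(stat.values, params))


def _relabelings(n_case: int, n_total: int, scheme: PermutationScheme,
                 rng: np.random.Generator):
    """Yield pseudo-case index arrays; exhaustive when the requested number of
    permutations exceeds the number of distinct relabelings."""
    n_distinct = comb(n_total, n_case)
    if scheme.n_perm >= n_distinct:
        warnings.warn(
            f"n_perm={scheme.n_perm} >= {n_distinct} distinct relabelings; "
            "using exhaustive enumeration", stacklevel=2)
        for c in combinations(range(n_total), n_case):
            yield np.array(c)
    else:
        for _ in range(scheme.n_perm):
            yield rng.permutation(n_total)[:n_case]


def permutation_fwe(case_maps: list[ScalarVolume],
                    control_maps: list[ScalarVolume],
                    scheme: PermutationScheme | None = None,
                    params: TfceParams | None = None,
                    mask: BinaryMask | None = None) -> SpecificityResult:
    """Two-group TFCE permutation test with strong FWE control.

    For each relabelling of the pooled maps the two-sample t-map and its TFCE
    are recomputed; the joint null distribution of the maximum TFCE over the
    mask and over both contrast directions converts observed TFCE values into
    FWE-corrected p-values ``(1 + #{perm max >= observed}) / (n_perm + 1)``.
    Deterministic given ``scheme.rng_seed``.
    """
    scheme = scheme or PermutationScheme()
    params = params or TfceParams()
    grid = case_maps[0].grid
    t_obs_vol = two_sample_glm_tmap(case_maps, control_maps)
    if mask is None:
        mask = BinaryMask(grid, np.ones(grid.dims, bool), label="full")
    grid.require_matches(mask.grid, "mask and maps")
    m = mask.membership

    n1, n2 = len(case_maps), len(control_maps)
    pooled = np.stack([np.asarray(v.values, float).reshape(grid.dims)
                       for v in case_maps + control_maps])
    pooled_masked = pooled * m  # zero outside the analysis mask

    t_obs = np.asarray(t_obs_vol.values) * m
    tfce_pos = _tfce_array(t_obs, params)
    tfce_neg = _tfce_array(-t_obs, params)

    rng = np.random.default_rng(scheme.rng_seed)
    all_idx = np.arange(n1 + n2)
    max_stats = []
    for case_idx in _relabelings(n1, n1 + n2, scheme, rng):
        ctrl_idx = np.setdiff1d(all_idx, case_idx, assume_unique=True)
        t_p = _two_sample_t(pooled_masked[case_idx], pooled_masked[ctrl_idx])
        max_stats.append(max(_tfce_array(t_p, params).max(initial=0.0),
                             _tfce_array(-t_p, params).max(initial=0.0)))
    max_stats = np.sort(np.asarray(max_stats))
    n_eff = max_stats.size

    def _p(tf: np.ndarray) -> np.ndarray:
        count_ge = n_eff - np.searchsorted(max_stats, tf.ravel(), side="left")
        p = (1.0 + count_ge) / (n_eff + 1.0)
        return np.where(m.ravel(), p, 1.0).reshape(grid.dims)

    p_pos, p_neg = _p(tfce_pos), _p(tfce_neg)
    return SpecificityResult(
        group_t=t_obs_vol,
        tfce_pos=ScalarVolume(grid, tfce_pos),
        tfce_neg=ScalarVolume(grid, tfce_neg),
        fwe_p_pos=ScalarVolume(grid, p_pos),
        fwe_p_neg=ScalarVolume(grid, p_neg),
        significant_pos=BinaryMask(grid, p_pos < scheme.alpha, "specific+"),
        significant_neg=BinaryMask(grid, p_neg < scheme.alpha, "specific-"),
        scheme=scheme,
        df=n1 + n2 - 2,
    )


def sensitive_and_specific(sensitive: BinaryMask,
                           significant: BinaryMask) -> BinaryMask:
    """Voxels both connected to most case lesions and significantly more (or
    less) connected to case than control lesions — applied per direction."""
    out = intersect_masks(sensitive, significant)
    out.label = "sensitive&specific"
    return out
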