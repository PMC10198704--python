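"""Lesion network mapping (LNM) and coordinate network mapping (CNM).

Both pipelines share the same composition: seed -> normative-connectome group
t-map -> binarise at |t| >= t_thresh -> overlay the binary maps across seeds
(positive and negative connectivity separately) -> keep voxels connected to at
least ``k_min`` of the N seeds (the "sensitivity" network). For LNM the seeds
are traced lesion masks; for CNM each published study contributes a single
combined seed, the union of small spheres placed at every coordinate it
reports. The pipelines are fully deterministic: no randomness enters before
the specificity stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ale import FocusSet
from .connectome import NormativeConnectome, group_tmaps, threshold_network
from .grid import BinaryMask, GridMismatchError, ScalarVolume, make_sphere_seed, union_masks

__all__ = [
    "NetworkMapConfig",
    "NetworkMapResult",
    "overlap_map",
    "sensitivity_network",
    "combined_study_seed",
    "run_lnm",
    "run_cnm",
]

#: Default sensitivity ratio: the headline thresholds of 16/19 lesions and 6/7
#: studies are both ceil(0.84 * N).
DEFAULT_K_MIN_RATIO = 0.84


@dataclass(frozen=True)
class NetworkMapConfig:
    """Thresholds of the mapping pipeline.

    ``k_min=None`` resolves to ``ceil(0.84 * n_seeds)``, reproducing the
    16-of-19 (lesions) and 6-of-7 (studies) ratios at their native cohort
    sizes while staying meaningful for other N.
    """

    t_thresh: float = 7.0
    k_min: int | None = None
    sphere_radius_mm: float = 4.0

    def __post_init__(self) -> None:
        if self.t_thresh <= 0:
            raise ValueError(f"t_thresh must be positive, got {self.t_thresh}")
        if self.sphere_radius_mm <= 0:
            raise ValueError("sphere_radius_mm must be positive")

    def resolve_k_min(self, n_seeds: int) -> int:
        k = self.k_min if self.k_min is not None else math.ceil(
            DEFAULT_K_MIN_RATIO * n_seeds)
        if not 1 <= k <= n_seeds:
            raise ValueError(f"k_min={k} is outside [1, {n_seeds}]")
        return k


@dataclass
class NetworkMapResult:
    """Per-seed t-maps, direction-separated overlap counts and the sensitivity
    masks {overlap >= k_min}."""

    per_seed_t: list[ScalarVolume]
    overlap_pos: ScalarVolume
    overlap_neg: ScalarVolume
    sensitive_pos: BinaryMask
    sensitive_neg: BinaryMask
    k_min: int
    config: NetworkMapConfig

    @property
    def n_seeds(self) -> int:
        return len(self.per_seed_t)


def overlap_map(binary_maps: list[BinaryMask]) -> ScalarVolume:
    """Voxelwise count of member masks (the classic lesion-overlay map)."""
    if not binary_maps:
        raise ValueError("overlap_map requires a nonempty list")
    grid = binary_maps[0].grid
    counts = np.zeros(grid.dims, dtype=int)
    for m in binary_maps:
        grid.require_matches(m.grid, "binary maps")
        counts += m.membership
    return ScalarVolume(grid, counts)


def sensitivity_network(overlap: ScalarVolume, k_min: int, n_seeds: int | None = None,
                        label: str = "sensitive") -> BinaryMask:
    """Voxels reached by at least ``k_min`` seeds (inclusive)."""
    n_max = int(np.max(overlap.values)) if n_seeds is None else n_seeds
    if not 1 <= k_min <= max(n_max, 1):
        raise ValueError(f"k_min={k_min} is outside [1, {n_max}]")
    return BinaryMask(overlap.grid, np.asarray(overlap.values) >= k_min, label=label)


def _compose(conn: NormativeConnectome, seeds: list[BinaryMask],
             cfg: NetworkMapConfig) -> NetworkMapResult:
    k_min = cfg.resolve_k_min(len(seeds))
    t_maps = group_tmaps(conn, seeds)
    pos_masks, neg_masks = [], []
    for t_map, seed in zip(t_maps, seeds):
        pos, neg = threshold_network(t_map, cfg.t_thresh, label=seed.label)
        pos_masks.append(pos)
        neg_masks.append(neg)
    ov_pos = overlap_map(pos_masks)
    ov_neg = overlap_map(neg_masks)
    return NetworkMapResult(
        per_seed_t=t_maps,
        overlap_pos=ov_pos,
        overlap_neg=ov_neg,
        sensitive_pos=sensitivity_network(ov_pos, k_min, len(seeds), "sensitive+"),
        sensitive_neg=sensitivity_network(ov_neg, k_min, len(seeds), "sensitive-"),
        k_min=k_min,
        config=cfg,
    )


def run_lnm(conn: NormativeConnectome, lesions: list[BinaryMask],
            cfg: NetworkMapConfig | None = None) -> NetworkMapResult:
    """Lesion network mapping: one seed per traced lesion."""
    if len(lesions) < 2:
        raise ValueError("lesion network mapping needs >= 2 lesions")
    for m in lesions:
        if not conn.grid.matches(m.grid):
            raise GridMismatchError(
                f"lesion {m.label!r} is not on the connectome grid")
    return _compose(conn, lesions, cfg or NetworkMapConfig())


def combined_study_seed(fs: FocusSet, grid, radius_mm: float = 4.0) -> BinaryMask:
    """Union of spheres at every coordinate a study reports — one combined
    seed per study, pooling higher- and lower-volume coordinates."""
    spheres = [make_sphere_seed(f, radius_mm, grid) for f in fs.foci]
    return union_masks(spheres, label=fs.study_id)


def run_cnm(conn: NormativeConnectome, studies: list[FocusSet],
            cfg: NetworkMapConfig | None = None,
            direction: str | None = None) -> NetworkMapResult:
    """Coordinate network mapping: one combined sphere-union seed per study.

    ``direction`` optionally restricts the analysis to studies reporting
    higher- or lower-volume differences (a stratified mode); the default pools
    all reported coordinates regardless of direction.
    """
    if direction is not None:
        studies = [fs for fs in studies if fs.direction == direction]
    if len(studies) < 1:
        raise ValueError("coordinate network mapping needs >= 1 study")
    cfg = cfg or NetworkMapConfig()
    seeds = [combined_study_seed(fs, conn.grid, cfg.sphere_radius_mm)
             for fs in studies]
    if len(seeds) == 1:
        # single-study reduction: the composition still runs, with k_min = 1
        cfg1 = NetworkMapConfig(t_thresh=cfg.t_thresh, k_min=1,
                                sphere_radius_mm=cfg.sphere_radius_mm)
        return _compose(conn, seeds, cfg1)
    return _compose(conn, seeds, cfg)
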