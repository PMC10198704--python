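"""Conjunction of binary networks and spatial correlation of map sets.

The conjunction stage intersects the lesion-derived and coordinate-derived
networks (positive with positive, negative with negative) to isolate the
voxels every line of evidence agrees on. Spatial correlation compares two
collections of unthresholded t-maps voxel-by-voxel inside a mask — used to ask
whether independently assembled lesion sets map to similar networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grid import BinaryMask, ScalarVolume, intersect_masks

__all__ = ["ConjunctionResult", "conjunction", "conjoin_networks",
           "spatial_correlation"]


@dataclass
class ConjunctionResult:
    positive: BinaryMask
    negative: BinaryMask
    provenance: tuple[str, str]


def conjunction(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    """Voxelwise AND of two binary networks on one grid."""
    out = intersect_masks(a, b)
    out.label = f"({a.label})&({b.label})" if (a.label or b.label) else ""
    return out


def conjoin_networks(pos_a: BinaryMask, neg_a: BinaryMask,
                     pos_b: BinaryMask, neg_b: BinaryMask,
                     labels: tuple[str, str] = ("A", "B")) -> ConjunctionResult:
    """Direction-respecting conjunction of two signed networks: positive with
    positive, negative with negative, never across signs."""
    return ConjunctionResult(
        positive=conjunction(pos_a, pos_b),
        negative=conjunction(neg_a, neg_b),
        provenance=labels,
    )


def spatial_correlation(set_a: list[ScalarVolume], set_b: list[ScalarVolume],
                        mask: BinaryMask) -> tuple[float, np.ndarray]:
    """Cross-set Pearson correlations of unthresholded maps over in-mask
    voxels.

    Returns ``(summary, matrix)`` where ``matrix[i, j]`` is the correlation of
    ``set_a[i]`` with ``set_b[j]`` and the summary is the inverse Fisher
    transform of the mean Fisher z over all defined pairs. Constant maps give
    undefined correlations; those pairs are NaN in the matrix and excluded
    from the summary with a warning.
    """
    if not set_a or not set_b:
        raise ValueError("both map sets must be nonempty")
    idx = mask.flat_indices

    def _stack(maps):
        for v in maps:
            mask.grid.require_matches(v.grid, "maps and mask")
        x = np.stack([np.asarray(v.values, float).ravel()[idx] for v in maps])
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(sd > 0, (x - mu) / sd, np.nan)
        return z, sd.ravel()

    za, sa = _stack(set_a)
    zb, sb = _stack(set_b)
    n_dropped = int((sa == 0).sum() + (sb == 0).sum())
    if n_dropped:
        warnings.warn(
            f"{n_dropped} constant map(s): their correlations are undefined "
            "and excluded from the summary", stacklevel=2)
    matrix = np.clip((za @ zb.T) / idx.size, -1.0, 1.0)
    finite = matrix[np.isfinite(matrix)]
    if finite.size == 0:
        raise ValueError("no defined map pairs (all maps constant?)")
    # Fisher-average the pairwise correlations
    z = np.arctanh(np.clip(finite, -1 + 1e-12, 1 - 1e-12))
    return float(np.tanh(z.mean())), matrix
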