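"""Normative connectome storage and seed-based group t-maps.

The normative connectome is a set of healthy-subject resting-state time series
over a shared brain mask. Network mapping extracts the mean BOLD time course
within a seed (a lesion tracing or a combined coordinate seed), correlates it
with every in-mask voxel per subject, Fisher-z transforms the correlations and
summarises them with a voxelwise one-sample t across subjects. Thresholding
that t-map at |t| >= 7 yields the binarised positive/negative connectivity
masks used by the overlap stages; with a 1000-subject connectome that
threshold corresponds to a whole-brain Bonferroni-corrected p on the order of
1e-6.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .grid import BinaryMask, ScalarVolume, VolumeGrid, load_mask, save_mask

__all__ = [
    "NormativeConnectome",
    "SeedConnectivityResult",
    "seed_timecourse",
    "subject_correlation_map",
    "group_tmap",
    "group_tmaps",
    "threshold_network",
    "whole_brain_corrected_p",
    "save_connectome",
    "load_connectome",
]

#: Correlations are clipped to +/-(1 - R_CLIP_EPS) before atanh so Fisher z
#: stays finite even for degenerate (self-seed) voxels.
R_CLIP_EPS = 1e-6
#: Sentinel |t| assigned when the across-subject z spread is exactly zero but
#: the mean is not (cannot happen with real data; documented, not silent).
T_SENTINEL = 1e6


@dataclass
class NormativeConnectome:
    """Per-subject time x in-mask-voxel matrices over one brain mask."""

    grid: VolumeGrid
    brain_mask: BinaryMask
    subjects: list[np.ndarray]

    def __post_init__(self) -> None:
        self.grid.require_matches(self.brain_mask.grid, "connectome and brain mask")
        n_vox = self.brain_mask.size
        for i, ts in enumerate(self.subjects):
            ts = np.asarray(ts)
            if ts.ndim != 2 or ts.shape[1] != n_vox:
                raise ValueError(
                    f"subject {i}: matrix shape {ts.shape} does not match "
                    f"brain mask size {n_vox}"
                )
            self.subjects[i] = ts

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def mask_flat_indices(self) -> np.ndarray:
        return self.brain_mask.flat_indices

    def seed_columns(self, seed: BinaryMask) -> np.ndarray:
        """Columns (in brain-mask order) covered by a seed; error if the seed
        misses the brain mask entirely."""
        self.grid.require_matches(seed.grid, "seed and connectome")
        cols = np.flatnonzero(
            (seed.membership & self.brain_mask.membership).ravel()[
                self.brain_mask.flat_indices
            ]
        )
        if cols.size == 0:
            raise ValueError(
                f"seed {seed.label!r} has no voxels inside the brain mask"
            )
        return cols

    def embed(self, in_mask_values: np.ndarray, fill: float = 0.0) -> ScalarVolume:
        """Scatter an in-mask vector back into a full 3-D volume."""
        out = np.full(self.grid.n_voxels, fill, dtype=float)
        out[self.mask_flat_indices] = in_mask_values
        return ScalarVolume(self.grid, out.reshape(self.grid.dims))


@dataclass
class SeedConnectivityResult:
    """Per-subject seed correlation fields plus the group one-sample t-map."""

    seed: BinaryMask
    per_subject_r: np.ndarray  # (n_subjects, n_in_mask_voxels)
    group_t: ScalarVolume
    df: int


def seed_timecourse(subject_ts: np.ndarray, seed: BinaryMask,
                    brain_mask: BinaryMask) -> np.ndarray:
    """Unweighted mean BOLD series across the seed's in-mask voxels."""
    seed.grid.require_matches(brain_mask.grid, "seed and brain mask")
    cols = np.flatnonzero(
        (seed.membership & brain_mask.membership).ravel()[brain_mask.flat_indices]
    )
    if cols.size == 0:
        raise ValueError(f"seed {seed.label!r} has no voxels inside the brain mask")
    return np.asarray(subject_ts, dtype=float)[:, cols].mean(axis=1)


def _zscore_columns(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centre/scale each column; zero-variance columns get scale 0 (so any
    correlation against them is 0 by construction). Returns (z, sd)."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (x - mu) / sd, 0.0)
    return z, sd


def subject_correlation_map(subject_ts: np.ndarray, seed: BinaryMask,
                            brain_mask: BinaryMask) -> np.ndarray:
    """Pearson r of the seed time course with every in-mask voxel series.

    Zero-variance voxels map to r = 0; a zero-variance seed course is an error
    because the whole map would be undefined.
    """
    course = seed_timecourse(subject_ts, seed, brain_mask)
    if course.size < 3:
        raise ValueError("need at least 3 time points for a correlation")
    sd = course.std()
    if sd == 0:
        raise ValueError(f"seed {seed.label!r} time course has zero variance")
    course_z = (course - course.mean()) / sd
    ts_z, _ = _zscore_columns(subject_ts)
    return np.clip(course_z @ ts_z / course.size, -1.0, 1.0)


def _t_from_moments(mean: np.ndarray, sd: np.ndarray, n: int) -> np.ndarray:
    """One-sample t from across-subject moments with documented degenerate
    handling: an (effectively) zero spread with nonzero mean maps to the
    +/-T_SENTINEL sentinel, zero mean with zero spread to 0. The degeneracy
    test is relative (sd <= 1e-6 |mean|) so floating-point cancellation in
    the accumulating code path cannot produce astronomically large t values.
    """
    degenerate = sd <= np.abs(mean) * 1e-6
    safe = ~degenerate & (sd > 0)
    t = np.divide(mean * np.sqrt(n), sd, out=np.zeros_like(mean), where=safe)
    return np.where(degenerate,
                    np.where(mean != 0, np.sign(mean) * T_SENTINEL, 0.0), t)


def _one_sample_t_from_r(r: np.ndarray) -> np.ndarray:
    """Fisher-z the subject correlations and take the voxelwise one-sample t."""
    z = np.arctanh(np.clip(r, -(1.0 - R_CLIP_EPS), 1.0 - R_CLIP_EPS))
    n = z.shape[0]
    return _t_from_moments(z.mean(axis=0), z.std(axis=0, ddof=1), n)


def group_tmap(conn: NormativeConnectome, seed: BinaryMask) -> SeedConnectivityResult:
    """Seed-connectivity group t-map: subject r -> Fisher z -> one-sample t
    across subjects (df = n - 1)."""
    if conn.n_subjects < 3:
        raise ValueError(f"need >= 3 subjects, got {conn.n_subjects}")
    r = np.stack(
        [subject_correlation_map(ts, seed, conn.brain_mask) for ts in conn.subjects]
    )
    t = _one_sample_t_from_r(r)
    return SeedConnectivityResult(
        seed=seed, per_subject_r=r, group_t=conn.embed(t), df=conn.n_subjects - 1
    )


def group_tmaps(conn: NormativeConnectome, seeds: list[BinaryMask]) -> list[ScalarVolume]:
    """Group t-maps for many seeds in one pass over the connectome.

    Equivalent to ``[group_tmap(conn, s).group_t for s in seeds]`` but each
    subject's time series is standardised once and all seed courses are
    correlated against it with a single matrix product.
    """
    if conn.n_subjects < 3:
        raise ValueError(f"need >= 3 subjects, got {conn.n_subjects}")
    cols = [conn.seed_columns(s) for s in seeds]
    n_seed, n_vox = len(seeds), conn.brain_mask.size
    z_sum = np.zeros((n_seed, n_vox))
    z_sq = np.zeros((n_seed, n_vox))
    n = conn.n_subjects
    for ts in conn.subjects:
        ts = np.asarray(ts, dtype=float)
        courses = np.stack([ts[:, c].mean(axis=1) for c in cols])  # (S, T)
        sd = courses.std(axis=1)
        if np.any(sd == 0):
            bad = seeds[int(np.argmax(sd == 0))]
            raise ValueError(f"seed {bad.label!r} time course has zero variance")
        courses_z = (courses - courses.mean(axis=1, keepdims=True)) / sd[:, None]
        ts_z, _ = _zscore_columns(ts)
        r = np.clip(courses_z @ ts_z / ts.shape[0], -1.0, 1.0)
        z = np.arctanh(np.clip(r, -(1.0 - R_CLIP_EPS), 1.0 - R_CLIP_EPS))
        z_sum += z
        z_sq += z * z
    mean = z_sum / n
    var = (z_sq - n * mean**2) / (n - 1)
    sd = np.sqrt(np.maximum(var, 0.0))
    t = _t_from_moments(mean, sd, n)
    return [conn.embed(t[i]) for i in range(n_seed)]


def threshold_network(t_map: ScalarVolume, t_thresh: float = 7.0,
                      label: str = "") -> tuple[BinaryMask, BinaryMask]:
    """Binarise a t-map into (positive, negative) masks at +/- ``t_thresh``
    with inclusive boundaries; the two masks are disjoint by construction."""
    if t_thresh <= 0:
        raise ValueError(f"t_thresh must be positive, got {t_thresh}")
    vals = np.asarray(t_map.values, dtype=float)
    pos = BinaryMask(t_map.grid, vals >= t_thresh, label=f"{label}+" if label else "")
    neg = BinaryMask(t_map.grid, vals <= -t_thresh, label=f"{label}-" if label else "")
    return pos, neg


def whole_brain_corrected_p(t_value: float, n_subjects: int, n_voxels: int) -> float:
    """Bonferroni-corrected two-sided one-sample p for a given t threshold.

    At t = 7 with n = 1000 subjects over a ~2.3e5-voxel brain mask this is on
    the order of 1e-6, which is what makes the |t| >= 7 binarisation a
    whole-brain FWE-corrected cut.
    """
    p_two_sided = 2.0 * stats.t.sf(abs(t_value), df=n_subjects - 1)
    return float(min(1.0, p_two_sided * n_voxels))


# ---------------------------------------------------------------------------
# on-disk layout: directory with brain_mask.nii.gz, one array per subject and
# a manifest (tab-separated: subject_id, path, T)
# ---------------------------------------------------------------------------

def save_connectome(conn: NormativeConnectome, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_mask(conn.brain_mask, directory / "brain_mask.nii.gz")
    rows = []
    for i, ts in enumerate(conn.subjects):
        name = f"subject_{i:04d}.npy"
        np.save(directory / name, np.asarray(ts, dtype=np.float32))
        rows.append({"subject_id": f"sub-{i:04d}", "path": name, "T": ts.shape[0]})
    pd.DataFrame(rows).to_csv(directory / "manifest.tsv", sep="\t", index=False)


def load_connectome(directory) -> NormativeConnectome:
    directory = Path(directory)
    mask = load_mask(directory / "brain_mask.nii.gz", label="brain")
    manifest = pd.read_csv(directory / "manifest.tsv", sep="\t")
    for col in ("subject_id", "path", "T"):
        if col not in manifest.columns:
            raise ValueError(f"connectome manifest is missing column {col!r}")
    subjects = []
    for _, row in manifest.iterrows():
        ts = np.load(directory / str(row["path"]))
        if ts.shape[0] != int(row["T"]):
            raise ValueError(
                f"{row['subject_id']}: manifest says T={row['T']} "
                f"but array has {ts.shape[0]} time points"
            )
        subjects.append(np.asarray(ts, dtype=float))
    return NormativeConnectome(mask.grid, mask, subjects)
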