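"""Group validation on resting-state fMRI: denoising, seed maps, covariate GLM.

Takes per-participant MNI-normalised BOLD matrices (preprocessing such as
realignment and normalisation is assumed done upstream), applies light
denoising — motion censoring at a framewise-displacement threshold, linear
detrend, nuisance regression (white matter / CSF means and their first
derivatives), band-pass filtering — screens out participants with too little
uncensored data, computes Fisher-z seed connectivity maps, and compares the
two groups with a voxelwise GLM controlling for age, sex and acquisition site.
Cluster-extent family-wise error is controlled by Freedman–Lane permutation of
the covariate-adjusted data using the maximum-cluster-size null over both
contrast directions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .connectome import R_CLIP_EPS
from .grid import BinaryMask, ScalarVolume, VolumeGrid, connected_components
from .inference import PermutationScheme

__all__ = [
    "ParticipantScan",
    "DenoiseConfig",
    "CensorResult",
    "Cluster",
    "GroupComparisonResult",
    "framewise_displacement",
    "censor_and_screen",
    "denoise",
    "participant_fz_map",
    "group_difference_clusters",
    "motion_comparison",
    "read_motion_table",
    "read_covariates_table",
]

#: Radius (mm) of the sphere onto which rotational displacement is projected
#: when summarising head motion as a scalar framewise displacement.
FD_ROTATION_RADIUS_MM = 50.0


@dataclass
class ParticipantScan:
    """One participant's (already MNI-normalised) in-mask BOLD matrix plus
    motion, nuisance and covariate information."""

    participant_id: str
    bold: np.ndarray        # (T, V) over the brain mask
    motion: np.ndarray      # (T, 6): 3 translations mm, 3 rotations radians
    nuisance: np.ndarray    # (T, k): WM mean, CSF mean, first derivatives...
    tr_seconds: float
    age: float
    sex: str
    site: str
    group: str              # 'patient' | 'control'

    def __post_init__(self) -> None:
        self.bold = np.asarray(self.bold, dtype=float)
        self.motion = np.asarray(self.motion, dtype=float)
        self.nuisance = np.asarray(self.nuisance, dtype=float)
        t = self.bold.shape[0]
        if self.motion.shape != (t, 6):
            raise ValueError(
                f"{self.participant_id}: motion table must be (T, 6), "
                f"got {self.motion.shape} for T={t}")
        if self.nuisance.shape[0] != t:
            raise ValueError(f"{self.participant_id}: nuisance rows != T")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.group not in ("patient", "control"):
            raise ValueError(f"group must be patient|control, got {self.group!r}")


@dataclass(frozen=True)
class DenoiseConfig:
    fd_thresh_mm: float = 0.5
    min_volumes: int = 300
    band_hz: tuple[float, float] = (0.008, 0.09)
    discard_initial: int = 4

    def validate_for_tr(self, tr_seconds: float) -> None:
        lo, hi = self.band_hz
        nyquist = 0.5 / tr_seconds
        if not 0.0 < lo < hi < nyquist:
            raise ValueError(
                f"band {self.band_hz} must satisfy 0 < low < high < "
                f"Nyquist ({nyquist:.3f} Hz)")


@dataclass
class CensorResult:
    included: bool
    kept_frames: np.ndarray  # indices into the post-discard series
    fd: np.ndarray           # FD per post-discard frame
    n_kept: int


def framewise_displacement(motion: np.ndarray) -> np.ndarray:
    """Power-style framewise displacement: sum of absolute first differences
    of the 3 translations (mm) plus the 3 rotations (radians) projected onto
    a 50 mm sphere. FD of the first frame is 0."""
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion table must be (T, 6), got {motion.shape}")
    d = np.abs(np.diff(motion, axis=0))
    fd = d[:, :3].sum(axis=1) + FD_ROTATION_RADIUS_MM * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def censor_and_screen(scan: ParticipantScan,
                      cfg: DenoiseConfig | None = None) -> CensorResult:
    """Discard initial frames, censor frames with FD above threshold, and
    screen the participant on the amount of remaining data (kept at exactly
    ``min_volumes``)."""
    cfg = cfg or DenoiseConfig()
    sl = slice(cfg.discard_initial, None)
    fd = framewise_displacement(scan.motion[sl])
    kept = np.flatnonzero(fd <= cfg.fd_thresh_mm)
    return CensorResult(
        included=kept.size >= cfg.min_volumes,
        kept_frames=kept,
        fd=fd,
        n_kept=int(kept.size),
    )


def _drop_collinear(x: np.ndarray, what: str) -> np.ndarray:
    """Greedily drop columns that do not increase matrix rank."""
    keep: list[int] = []
    r = 0
    for j in range(x.shape[1]):
        cand = x[:, keep + [j]]
        r_new = np.linalg.matrix_rank(cand)
        if r_new > r:
            keep.append(j)
            r = r_new
    if len(keep) < x.shape[1]:
        warnings.warn(
            f"{what}: dropped {x.shape[1] - len(keep)} collinear column(s)",
            stacklevel=3)
    return x[:, keep]


def _bandpass(data: np.ndarray, tr: float, band: tuple[float, float]) -> np.ndarray:
    """Zero-phase frequency-domain band-pass along axis 0: FFT coefficients
    outside [low, high] Hz are zeroed (the DC bin is always removed)."""
    t = data.shape[0]
    freqs = np.fft.rfftfreq(t, d=tr)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    spec = np.fft.rfft(data, axis=0)
    spec[~keep] = 0.0
    return np.fft.irfft(spec, n=t, axis=0)


def denoise(scan: ParticipantScan, cfg: DenoiseConfig | None = None,
            censor: CensorResult | None = None) -> np.ndarray:
    """Censored, detrended, nuisance-regressed, band-pass-filtered BOLD.

    Censoring deletes high-motion volumes before any filtering; regression of
    the nuisance columns strictly precedes the band-pass, mirroring the
    regress-then-filter denoising order. Returns the cleaned (T_kept, V)
    matrix.
    """
    cfg = cfg or DenoiseConfig()
    cfg.validate_for_tr(scan.tr_seconds)
    if censor is None:
        censor = censor_and_screen(scan, cfg)
    sl = slice(cfg.discard_initial, None)
    bold = scan.bold[sl][censor.kept_frames]
    nuis = scan.nuisance[sl][censor.kept_frames]
    if not np.all(np.isfinite(nuis)):
        raise ValueError(f"{scan.participant_id}: nuisance regressors not finite")

    bold = signal.detrend(bold, axis=0, type="linear")
    nuis = signal.detrend(nuis, axis=0, type="linear")
    design = np.column_stack([np.ones(bold.shape[0]), nuis])
    design = _drop_collinear(design, f"{scan.participant_id} nuisance matrix")
    beta, *_ = np.linalg.lstsq(design, bold, rcond=None)
    resid = bold - design @ beta
    return _bandpass(resid, scan.tr_seconds, cfg.band_hz)


def participant_fz_map(cleaned: np.ndarray, seed: BinaryMask,
                       brain_mask: BinaryMask) -> np.ndarray:
    """Fisher-z seed connectivity map of one participant (in-mask vector)."""
    from .connectome import subject_correlation_map

    r = subject_correlation_map(cleaned, seed, brain_mask)
    return np.arctanh(np.clip(r, -(1.0 - R_CLIP_EPS), 1.0 - R_CLIP_EPS))


# ---------------------------------------------------------------------------
# covariate GLM with permutation cluster-extent FWE
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    peak_mm: tuple[float, float, float]
    peak_t: float
    size_voxels: int
    fwe_p: float
    sign: int  # +1 patients > controls, -1 patients < controls


@dataclass
class GroupComparisonResult:
    group_t: ScalarVolume
    clusters: list[Cluster]
    per_group_cluster_fz: pd.DataFrame  # participant x cluster mean Fz + group
    df: int
    t_height: float
    scheme: PermutationScheme


def _build_design(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Design matrix: intercept, group (patient=1), centred age, dummy-coded
    sex and site (first level dropped). The group column is index 1."""
    required = {"group", "age", "sex", "site"}
    missing = required - set(covariates.columns)
    if missing:
        raise ValueError(f"covariate table is missing columns {sorted(missing)}")
    site_by_group = pd.crosstab(covariates["site"], covariates["group"])
    lonely = site_by_group.index[(site_by_group > 0).sum(axis=1) < 2].tolist()
    if lonely:
        warnings.warn(
            f"site(s) {lonely} contain only one group; the site column is "
            "retained but group and site are partially confounded",
            stacklevel=3)
    cols = [np.ones(len(covariates)),
            (covariates["group"].to_numpy() == "patient").astype(float),
            covariates["age"].to_numpy(float) - covariates["age"].mean()]
    names = ["intercept", "group", "age"]
    for col in ("sex", "site"):
        dummies = pd.get_dummies(covariates[col], prefix=col, drop_first=True)
        for name in dummies.columns:
            cols.append(dummies[name].to_numpy(float))
            names.append(name)
    x = np.column_stack(cols)
    # drop covariate columns that add no rank (constant age, single-level
    # factors, redundant dummies) so the contrast stays identifiable; the
    # intercept and group columns are always kept
    keep = [0, 1]
    r = np.linalg.matrix_rank(x[:, keep])
    for j in range(2, x.shape[1]):
        r_new = np.linalg.matrix_rank(x[:, keep + [j]])
        if r_new > r:
            keep.append(j)
            r = r_new
    if len(keep) < x.shape[1]:
        dropped = [names[j] for j in range(x.shape[1]) if j not in keep]
        warnings.warn(f"dropping uninformative covariate column(s) {dropped}",
                      stacklevel=3)
    return x[:, keep], [names[j] for j in keep]


def _glm_group_t(x: np.ndarray, y: np.ndarray, xtx_inv: np.ndarray,
                 pinv_x: np.ndarray, c: np.ndarray, dof: int) -> np.ndarray:
    beta = pinv_x @ y                       # (k, V)
    resid = y - x @ beta
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * float(c @ xtx_inv @ c))
    return np.divide(c @ beta, se, out=np.zeros_like(se), where=se > 0)


def _cluster_sizes_and_labels(t3d: np.ndarray, mask3d: np.ndarray, t_crit: float,
                              connectivity: int):
    out = []
    for sign in (1, -1):
        supra = (sign * t3d >= t_crit) & mask3d
        labels, sizes = connected_components(supra, connectivity)
        out.append((sign, labels, sizes))
    return out


def group_difference_clusters(fz_maps: np.ndarray, covariates: pd.DataFrame,
                              grid: VolumeGrid, mask: BinaryMask,
                              height_p: float = 0.001,
                              cluster_alpha: float = 0.05,
                              scheme: PermutationScheme | None = None,
                              connectivity: int = 26) -> GroupComparisonResult:
    """Voxelwise covariate GLM for the patient-control contrast with
    permutation cluster-extent FWE.

    ``fz_maps`` is (n_participants, V) over the brain mask, rows aligned with
    ``covariates`` (columns group, age, sex, site). Suprathreshold clusters
    are formed at the two-sided height threshold |t| >= t(1 - height_p/2, df),
    separately per sign; their sizes are compared against the Freedman–Lane
    permutation null of the maximum cluster size over both signs.
    """
    scheme = scheme or PermutationScheme()
    fz_maps = np.asarray(fz_maps, dtype=float)
    n = fz_maps.shape[0]
    if len(covariates) != n:
        raise ValueError("covariate rows do not match number of Fz maps")
    counts = covariates["group"].value_counts()
    if counts.get("patient", 0) < 3 or counts.get("control", 0) < 3:
        raise ValueError("need >= 3 participants per group")

    x, names = _build_design(covariates)
    k = x.shape[1]
    dof = n - np.linalg.matrix_rank(x)
    c = np.zeros(k)
    c[1] = 1.0
    xtx_inv = np.linalg.inv(x.T @ x)
    pinv_x = xtx_inv @ x.T
    t_crit = float(stats.t.ppf(1.0 - height_p / 2.0, dof))

    m3d = mask.membership
    in_mask = mask.flat_indices
    if fz_maps.shape[1] != in_mask.size:
        raise ValueError("fz_maps must have one column per in-mask voxel")
    t_obs = _glm_group_t(x, fz_maps, xtx_inv, pinv_x, c, dof)
    t3d = np.zeros(grid.n_voxels)
    t3d[in_mask] = t_obs
    t3d = t3d.reshape(grid.dims)
    y_for_perm = fz_maps

    observed = _cluster_sizes_and_labels(t3d, m3d, t_crit, connectivity)

    # Freedman–Lane: residualise on the nuisance design (everything but the
    # group column), permute participant rows of the residuals, refit.
    z = np.delete(x, 1, axis=1)
    rz = np.eye(n) - z @ np.linalg.pinv(z)
    y_res = rz @ y_for_perm
    rng = np.random.default_rng(scheme.rng_seed)
    null_max = np.zeros(scheme.n_perm, dtype=int)
    for j in range(scheme.n_perm):
        perm = rng.permutation(n)
        t_p = _glm_group_t(x, y_res[perm], xtx_inv, pinv_x, c, dof)
        t_p3d = np.zeros(grid.n_voxels)
        t_p3d[in_mask] = t_p
        t_p3d = t_p3d.reshape(grid.dims)
        best = 0
        for _, _, sizes in _cluster_sizes_and_labels(t_p3d, m3d, t_crit,
                                                     connectivity):
            if sizes.size:
                best = max(best, int(sizes.max()))
        null_max[j] = best

    clusters: list[Cluster] = []
    fz_cols: dict[str, np.ndarray] = {}
    for sign, labels, sizes in observed:
        for lbl, size in enumerate(sizes, start=1):
            member = labels == lbl
            tvals = t3d[member]
            peak_pos = np.argwhere(member)[np.argmax(sign * tvals)]
            fwe_p = (1.0 + int((null_max >= size).sum())) / (scheme.n_perm + 1.0)
            clusters.append(Cluster(
                peak_mm=tuple(grid.voxel_to_world(peak_pos)),
                peak_t=float(tvals[np.argmax(sign * tvals)]),
                size_voxels=int(size),
                fwe_p=float(fwe_p),
                sign=sign,
            ))
            member_cols = np.flatnonzero(member.ravel()[in_mask])
            fz_cols[f"cluster_{len(clusters)}"] = y_for_perm[:, member_cols].mean(axis=1)
    clusters_order = np.argsort([-cl.size_voxels for cl in clusters])
    clusters = [clusters[i] for i in clusters_order]
    fz_df = pd.DataFrame(
        {f"cluster_{rank + 1}": fz_cols[f"cluster_{orig + 1}"]
         for rank, orig in enumerate(clusters_order)})
    fz_df.insert(0, "group", covariates["group"].to_numpy())

    t_full = np.zeros(grid.n_voxels)
    t_full[in_mask] = t_obs
    return GroupComparisonResult(
        group_t=ScalarVolume(grid, t_full.reshape(grid.dims)),
        clusters=clusters,
        per_group_cluster_fz=fz_df,
        df=int(dof),
        t_height=t_crit,
        scheme=scheme,
    )


#: Confounds-style column names accepted by the motion reader, in the order
#: the pipeline expects (translations mm, then rotations radians).
_CONFOUNDS_MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z",
                             "rot_x", "rot_y", "rot_z"]


def read_motion_table(path) -> np.ndarray:
    """Read a motion-parameter table as a (T, 6) array.

    Accepts either headerless 6-column whitespace/comma-delimited text
    (translations mm then rotations radians) or a confounds-style table with
    named columns trans_x..rot_z. Rotations must be in radians; values whose
    magnitude exceeds pi are a strong sign of degrees and raise an error,
    values above 0.5 rad (~29 deg) trigger a warning.
    """
    df = pd.read_csv(path, sep=None, engine="python", header=None)
    first = df.iloc[0].astype(str)
    if first.str.contains("[A-Za-z]").any():  # named header row
        df = pd.read_csv(path, sep=None, engine="python")
        missing = [c for c in _CONFOUNDS_MOTION_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: motion table is missing columns {missing}")
        motion = df[_CONFOUNDS_MOTION_COLUMNS].to_numpy(float)
    else:
        motion = df.to_numpy(float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(
            f"{path}: expected 6 motion columns, got shape {motion.shape}")
    max_rot = np.abs(motion[:, 3:]).max(initial=0.0)
    if max_rot > np.pi:
        raise ValueError(
            f"{path}: rotation magnitude {max_rot:.2f} exceeds pi; rotations "
            "must be in radians, not degrees")
    if max_rot > 0.5:
        warnings.warn(
            f"{path}: rotations reach {max_rot:.2f} rad (~{np.degrees(max_rot):.0f} deg); "
            "check that the source really uses radians", stacklevel=2)
    return motion


def read_covariates_table(path) -> pd.DataFrame:
    """Read a participant covariates table (id, age, sex, site, group)."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"id", "age", "sex", "site", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: covariates table is missing {sorted(missing)}")
    bad = set(df["group"].unique()) - {"patient", "control"}
    if bad:
        raise ValueError(f"{path}: unknown group labels {sorted(bad)}")
    return df


def motion_comparison(fd_means_patients, fd_means_controls) -> tuple[float, float]:
    """Two-sided pooled-variance two-sample t-test on mean framewise
    displacement; returns (t, p). Degenerate zero-variance data with equal
    means gives p = 1."""
    a = np.asarray(fd_means_patients, dtype=float)
    b = np.asarray(fd_means_controls, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 participants per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return 0.0, 1.0
        return float(np.sign(a[0] - b[0]) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
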