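"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates, at desk scale, the data the mapping pipelines consume:

* a miniature normative connectome whose subjects share two latent AR(1)
  signals projected through smooth spatial loading fields ("nodes"), including
  a negatively loaded node that emulates an anticorrelated cortical cluster;
* cohorts of spherical "lesions" placed inside designated network nodes, at
  control-network nodes, or at random off-network locations;
* jittered coordinate "studies" (foci around node centres plus decoys);
* a patient/control BOLD cohort with a tunable reduction of the coupling
  between the planted seed network and a designated target node, realistic
  motion traces with injected high-FD spikes, and balanced covariates.

Two latents drive the connectome: a "symptom" latent carrying the network to
be recovered, and a "shared" latent loading both the case-lesion sites and a
hub that control lesions are also connected to — the structure the
sensitivity-versus-specificity distinction needs. All generators are pure
functions of (config, truth, seed): identical inputs give byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .ale import FocusSet
from .connectome import NormativeConnectome
from .grid import BinaryMask, ScalarVolume, VolumeGrid, make_grid, make_sphere_seed
from .validation import ParticipantScan

__all__ = [
    "Node",
    "GroundTruth",
    "SyntheticConfig",
    "default_ground_truth",
    "make_connectome",
    "make_lesion_cohort",
    "make_coordinate_studies",
    "make_clinical_cohort",
]

#: Loadings below this value are cut to zero; the planted network "support"
#: (the recovery target for Dice) is exactly the set of voxels with
#: |symptom-latent loading| >= this cut.
SUPPORT_CUT = 0.05


@dataclass(frozen=True)
class Node:
    """A spherical-Gaussian loading blob.

    ``weights = (w_symptom, w_shared)`` are the loadings of the two latent
    time courses at the node centre; a negative symptom weight creates the
    anticorrelated node. Roles: 'lesion' (case lesions are placed here),
    'target' (pure symptom-network nodes), 'negative' (anticorrelated),
    'hub' (shared latent only — connected to case AND control lesions),
    'control' (control lesions are placed here), 'frontal_target' (no
    connectome loading; couples to the seed network only in the clinical
    cohort generator).
    """

    name: str
    center_mm: tuple[float, float, float]
    sigma_mm: float
    weights: tuple[float, float]
    role: str


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort shapes and generator settings (defaults mirror the study:
    19 case lesions, control sets 25/29/36, 7 studies / 77 foci, 21 patients
    vs 25 controls plus 2+2 high-motion exclusions, TR 0.8 s)."""

    dims: tuple[int, int, int] = (20, 24, 20)
    voxel_mm: float = 2.0
    n_subjects: int = 40
    T: int = 120
    n_case_lesions: int = 19
    n_control_lesions: tuple[int, int, int] = (25, 29, 36)
    lesion_radius_range_mm: tuple[float, float] = (2.0, 4.0)
    lesion_jitter_sd_mm: float = 2.0
    n_studies: int = 7
    foci_per_study: int = 11
    focus_jitter_sd_mm: float = 3.0
    decoys_per_study: int = 2
    study_n_range: tuple[int, int] = (15, 40)
    n_patients: int = 21
    n_controls: int = 25
    n_high_motion_patients: int = 2
    n_high_motion_controls: int = 2
    T_bold: int = 380
    tr_seconds: float = 0.8
    rho0: float = 0.7          # control-group seed->target latent coupling
    motion_step_sd_mm: float = 0.02
    motion_step_sd_rad: float = 2e-4
    spikes_per_scan: tuple[int, int] = (1, 5)      # uniform int range
    spike_amplitude_mm: float = 0.9
    high_motion_spike_fraction: float = 0.4
    sites: tuple[str, ...] = ("siteA", "siteB", "siteC")
    bold_smooth_fwhm_mm: float = 6.0   # upstream spatial smoothing emulated

    @classmethod
    def small(cls, **overrides) -> "SyntheticConfig":
        """Reduced problem sizes for repeated calibration/power simulations.

        Only sizes shrink (grid, time series, cohort counts); the noise
        model, effect sizes and all thresholds are untouched.
        """
        base = dict(
            dims=(12, 14, 12), n_subjects=16, T=100,
            n_case_lesions=10, n_control_lesions=(7, 7, 7),
            n_studies=5, foci_per_study=6, decoys_per_study=1,
            n_patients=21, n_controls=25,
            n_high_motion_patients=0, n_high_motion_controls=0,
            T_bold=160,
        )
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class GroundTruth:
    """Planted spatial/temporal structure of the synthetic world."""

    grid: VolumeGrid
    brain_mask: BinaryMask
    nodes: tuple[Node, ...]
    latent_ar1: float = 0.4
    noise_sd: float = 1.0
    group_effect_delta: float = 0.5   # fractional seed->target coupling loss
    rng_seed: int = 0
    # loading fields, one per latent, filled in by default_ground_truth
    w_symptom: np.ndarray = field(default=None, repr=False)
    w_shared: np.ndarray = field(default=None, repr=False)
    w_frontal: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not -1.0 < self.latent_ar1 < 1.0:
            raise ValueError("|latent_ar1| must be < 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.group_effect_delta <= 1.0:
            raise ValueError("group_effect_delta must be in [0, 1]")

    # -- derived masks ----------------------------------------------------
    @property
    def network_mask_pos(self) -> BinaryMask:
        """Support of positive symptom-latent loading: the planted network a
        positive sensitivity map should recover."""
        return BinaryMask(self.grid, self.w_symptom >= SUPPORT_CUT, "truth+")

    @property
    def network_mask_neg(self) -> BinaryMask:
        return BinaryMask(self.grid, self.w_symptom <= -SUPPORT_CUT, "truth-")

    def nodes_with_role(self, role: str) -> list[Node]:
        return [n for n in self.nodes if n.role == role]

    def node_support(self, node: Node) -> BinaryMask:
        g = _gaussian_field(self.grid, node.center_mm, node.sigma_mm)
        return BinaryMask(self.grid, g >= SUPPORT_CUT, node.name)


def _gaussian_field(grid: VolumeGrid, center_mm, sigma_mm: float) -> np.ndarray:
    """Flat-top blob exp(-(d^2 / 2 sigma^2)^2), truncated below SUPPORT_CUT.

    The quartic exponent keeps the loading near its peak value across most of
    the node and drops it to zero over a thin shell, so the planted support
    is a well-posed recovery target that does not depend delicately on where
    a statistical threshold lands inside a soft Gaussian tail.
    """
    idx = np.indices(grid.dims).reshape(3, -1).T
    world = grid.voxel_to_world(idx)
    d2 = ((world - np.asarray(center_mm, float)) ** 2).sum(axis=1)
    g = np.exp(-((d2 / (2.0 * sigma_mm**2)) ** 2))
    g[g < SUPPORT_CUT] = 0.0
    return g.reshape(grid.dims)


def _ellipsoid_brain_mask(grid: VolumeGrid, fill: float = 0.92) -> BinaryMask:
    idx = np.indices(grid.dims).reshape(3, -1).T
    world = grid.voxel_to_world(idx)
    half_extent = (np.asarray(grid.dims, float) - 1.0) / 2.0 * grid.voxel_size_mm
    semi = fill * half_extent
    inside = ((world / semi) ** 2).sum(axis=1) <= 1.0
    return BinaryMask(grid, inside.reshape(grid.dims), label="brain")


_DEFAULT_NODE_LAYOUT = (
    # name, centre as a fraction of the brain semi-axes, sigma mm, weights, role
    ("lesionL",  (-0.50, -0.22, -0.06), 3.0, (0.7, 0.7),  "lesion"),
    ("lesionR",  (+0.50, -0.22, -0.06), 3.0, (0.7, 0.7),  "lesion"),
    ("lesionM",  (+0.06, +0.22, -0.50), 3.0, (0.7, 0.7),  "lesion"),
    ("targetL",  (-0.50, +0.40, +0.40), 4.0, (1.0, 0.0),  "target"),
    ("targetR",  (+0.50, +0.40, +0.40), 4.0, (1.0, 0.0),  "target"),
    ("negative", (+0.06, -0.66, +0.40), 4.0, (-1.0, 0.0), "negative"),
    ("hub",      (-0.06, -0.66, -0.50), 3.0, (0.0, 1.0),  "hub"),
    ("controlL", (-0.72, +0.30, -0.40), 3.0, (0.0, 1.0),  "control"),
    ("controlR", (+0.72, +0.30, -0.40), 3.0, (0.0, 1.0),  "control"),
    ("frontal",  (+0.06, +0.74, +0.25), 4.0, (0.0, 0.0),  "frontal_target"),
)


def default_ground_truth(cfg: SyntheticConfig | None = None,
                         latent_ar1: float = 0.4, noise_sd: float = 1.0,
                         group_effect_delta: float = 0.5,
                         rng_seed: int = 0) -> GroundTruth:
    """Standard planted world on the config's grid: three case-lesion nodes,
    two pure symptom-network targets, one anticorrelated node, a shared hub,
    two control-lesion nodes, and a frontal validation target."""
    cfg = cfg or SyntheticConfig()
    grid = make_grid(cfg.dims, cfg.voxel_mm, centred=True)
    brain = _ellipsoid_brain_mask(grid)
    half_extent = (np.asarray(cfg.dims, float) - 1.0) / 2.0 * cfg.voxel_mm
    semi = 0.92 * half_extent
    nodes = []
    for name, frac, sigma, weights, role in _DEFAULT_NODE_LAYOUT:
        center = tuple(np.asarray(frac) * semi)
        nodes.append(Node(name, center, sigma, weights, role))
    w_sym = np.zeros(grid.dims)
    w_sha = np.zeros(grid.dims)
    w_fro = np.zeros(grid.dims)
    for node in nodes:
        g = _gaussian_field(grid, node.center_mm, node.sigma_mm)
        w_sym += node.weights[0] * g
        w_sha += node.weights[1] * g
        if node.role == "frontal_target":
            w_fro += g
    b = brain.membership
    w_sym *= b
    w_sha *= b
    w_fro *= b
    return GroundTruth(
        grid=grid, brain_mask=brain, nodes=tuple(nodes),
        latent_ar1=latent_ar1, noise_sd=noise_sd,
        group_effect_delta=group_effect_delta, rng_seed=rng_seed,
        w_symptom=w_sym, w_shared=w_sha, w_frontal=w_fro,
    )


def _ar1(rng: np.random.Generator, t: int, a: float, n_series: int = 1) -> np.ndarray:
    """Stationary AR(1) series with unit marginal variance, shape (t, n)."""
    x = np.empty((t, n_series))
    x[0] = rng.standard_normal(n_series)
    innov_sd = np.sqrt(1.0 - a * a)
    eps = rng.standard_normal((t - 1, n_series)) * innov_sd
    for i in range(1, t):
        x[i] = a * x[i - 1] + eps[i - 1]
    return x


def make_connectome(cfg: SyntheticConfig, truth: GroundTruth,
                    seed: int = 0) -> NormativeConnectome:
    """Normative connectome: per subject, two latent AR(1) courses projected
    through the planted loading fields plus white voxel noise. Voxels of the
    negatively loaded node receive the negated symptom latent via their
    negative loading."""
    rng = np.random.default_rng(seed)
    in_mask = truth.brain_mask.flat_indices
    w = np.stack([truth.w_symptom.ravel()[in_mask],
                  truth.w_shared.ravel()[in_mask]])  # (2, V)
    subjects = []
    for _ in range(cfg.n_subjects):
        latents = _ar1(rng, cfg.T, truth.latent_ar1, 2)  # (T, 2)
        ts = latents @ w + truth.noise_sd * rng.standard_normal(
            (cfg.T, in_mask.size))
        subjects.append(ts.astype(np.float32))
    return NormativeConnectome(truth.grid, truth.brain_mask, subjects)


def _random_in_mask_point(rng, mask: BinaryMask) -> np.ndarray:
    idx = np.argwhere(mask.membership)
    return mask.grid.voxel_to_world(idx[rng.integers(0, idx.shape[0])])


def make_lesion_cohort(truth: GroundTruth, cfg: SyntheticConfig,
                       placement: str, n_lesions: int | None = None,
                       seed: int = 0, max_retries: int = 200) -> list[BinaryMask]:
    """Spherical lesion masks.

    placement='in_network': jittered around the case-lesion nodes, each lesion
    guaranteed to intersect the planted symptom network support.
    placement='control_network': jittered around the control nodes (connected
    to the shared hub, not the symptom network).
    placement='off_network': uniform random in-brain centres whose lesion
    spheres avoid every node support ("node cores").
    placement='uniform': uniform random in-brain centres with no avoidance —
    used for exchangeable null cohorts where both groups must share one
    placement distribution.
    """
    rng = np.random.default_rng(seed)
    if placement == "in_network":
        anchors = truth.nodes_with_role("lesion")
        n = cfg.n_case_lesions if n_lesions is None else n_lesions
    elif placement == "control_network":
        anchors = truth.nodes_with_role("control")
        n = sum(cfg.n_control_lesions) if n_lesions is None else n_lesions
    elif placement in ("off_network", "uniform"):
        anchors = None
        n = cfg.n_case_lesions if n_lesions is None else n_lesions
    else:
        raise ValueError(f"unknown placement {placement!r}")

    node_support = np.zeros(truth.grid.dims, dtype=bool)
    for node in truth.nodes:
        if node.role != "frontal_target":
            node_support |= truth.node_support(node).membership
    net_support = (np.abs(truth.w_symptom) >= SUPPORT_CUT)

    lo_r, hi_r = cfg.lesion_radius_range_mm
    lesions: list[BinaryMask] = []
    for i in range(n):
        for attempt in range(max_retries):
            radius = rng.uniform(lo_r, hi_r)
            if anchors is not None:
                node = anchors[i % len(anchors)]
                center = (np.asarray(node.center_mm)
                          + rng.normal(0.0, cfg.lesion_jitter_sd_mm, 3))
            else:
                center = _random_in_mask_point(rng, truth.brain_mask)
            try:
                sphere = make_sphere_seed(center, radius, truth.grid,
                                          label=f"{placement}_{i:03d}")
            except ValueError:
                continue
            member = sphere.membership & truth.brain_mask.membership
            if member.sum() == 0:
                continue
            if placement == "in_network" and not (member & net_support).any():
                continue
            if placement == "off_network" and (member & node_support).any():
                continue
            lesions.append(BinaryMask(truth.grid, member,
                                      label=f"{placement}_{i:03d}"))
            break
        else:
            raise RuntimeError(
                f"could not place lesion {i} ({placement}) in {max_retries} tries")
    return lesions


def make_coordinate_studies(truth: GroundTruth, cfg: SyntheticConfig,
                            seed: int = 0) -> list[FocusSet]:
    """Coordinate 'studies': per study, foci at symptom-network node centres
    plus Gaussian jitter, padded with random in-brain decoy foci; directions
    assigned per node (the anticorrelated node reports 'higher' volume, the
    rest 'lower'); per-study sample sizes drawn from ``study_n_range``."""
    rng = np.random.default_rng(seed)
    network_nodes = [n for n in truth.nodes
                     if n.role in ("lesion", "target", "negative")]
    studies = []
    for s in range(cfg.n_studies):
        n_real = max(cfg.foci_per_study - cfg.decoys_per_study, 1)
        foci = []
        for j in range(n_real):
            node = network_nodes[j % len(network_nodes)]
            foci.append(np.asarray(node.center_mm)
                        + rng.normal(0.0, cfg.focus_jitter_sd_mm, 3))
        for _ in range(cfg.foci_per_study - n_real):
            foci.append(_random_in_mask_point(rng, truth.brain_mask))
        direction = "higher" if s % 3 == 2 else "lower"
        # clamp jittered foci back inside the brain so all foci are mappable
        clamped = []
        for f in foci:
            try:
                truth.grid.world_to_voxel(f)
                clamped.append(f)
            except ValueError:
                clamped.append(_random_in_mask_point(rng, truth.brain_mask))
        studies.append(FocusSet(
            study_id=f"study_{s + 1:02d}",
            foci=np.asarray(clamped),
            n_subjects=int(rng.integers(cfg.study_n_range[0],
                                        cfg.study_n_range[1] + 1)),
            direction=direction,
        ))
    return studies


def _motion_trace(rng, t: int, cfg: SyntheticConfig,
                  spike_frames: np.ndarray) -> np.ndarray:
    steps = np.column_stack([
        rng.normal(0.0, cfg.motion_step_sd_mm, (t, 3)),
        rng.normal(0.0, cfg.motion_step_sd_rad, (t, 3)),
    ])
    motion = np.cumsum(steps, axis=0)
    # a spike is a one-frame translation offset large enough that FD exceeds
    # the censoring threshold at the spike frame (and its return frame)
    motion[spike_frames, 0] += cfg.spike_amplitude_mm
    return motion


def make_clinical_cohort(truth: GroundTruth, cfg: SyntheticConfig,
                         seed: int = 0) -> list[ParticipantScan]:
    """Patient/control BOLD cohort with a planted coupling deficit.

    Voxel series are built from the connectome loading fields; in addition the
    frontal target node follows a course correlated rho with the symptom
    latent, where rho = rho0 for controls and rho0 * (1 - delta) for
    patients. Each frame is spatially smoothed (default 6 mm FWHM), emulating
    the smoothing applied by upstream fMRI preprocessing; this is what gives
    group t-maps the spatial coherence that cluster-extent inference relies
    on. White-matter/CSF artefact courses are mixed into all brain
    voxels and provided as nuisance regressors. Motion traces are random walks
    with injected high-FD spikes; designated high-motion participants receive
    spikes on a large fraction of frames so the data screen excludes them.
    Covariates: age ~ U(6, 17), random sex, sites cycled within group.
    """
    rng = np.random.default_rng(seed)
    grid = truth.grid
    in_mask = truth.brain_mask.flat_indices
    w_sym = truth.w_symptom.ravel()[in_mask]
    w_sha = truth.w_shared.ravel()[in_mask]
    w_fro = truth.w_frontal.ravel()[in_mask]
    t = cfg.T_bold

    groups = (["patient"] * (cfg.n_patients + cfg.n_high_motion_patients)
              + ["control"] * (cfg.n_controls + cfg.n_high_motion_controls))
    high_motion = ([False] * cfg.n_patients + [True] * cfg.n_high_motion_patients
                   + [False] * cfg.n_controls + [True] * cfg.n_high_motion_controls)

    scans = []
    site_counters = {"patient": 0, "control": 0}
    for i, (group, noisy) in enumerate(zip(groups, high_motion)):
        rho = cfg.rho0 * (1.0 - truth.group_effect_delta) \
            if group == "patient" else cfg.rho0
        latents = _ar1(rng, t, truth.latent_ar1, 3)  # symptom, shared, indep
        l_sym, l_sha, l_ind = latents.T
        l_fro = rho * l_sym + np.sqrt(1.0 - rho * rho) * l_ind
        wm = _ar1(rng, t, truth.latent_ar1, 1).ravel()
        csf = _ar1(rng, t, truth.latent_ar1, 1).ravel()
        artefact = 0.3 * (wm + csf)
        bold = (np.outer(l_sym, w_sym) + np.outer(l_sha, w_sha)
                + np.outer(l_fro, w_fro)
                + artefact[:, None]
                + truth.noise_sd * rng.standard_normal((t, in_mask.size)))
        if cfg.bold_smooth_fwhm_mm > 0:
            from scipy import ndimage
            sigma_vox = (cfg.bold_smooth_fwhm_mm
                         / (2.0 * np.sqrt(2.0 * np.log(2.0)))
                         / grid.voxel_size_mm)
            frame = np.zeros(grid.n_voxels)
            for j in range(t):
                frame[:] = 0.0
                frame[in_mask] = bold[j]
                sm = ndimage.gaussian_filter(frame.reshape(grid.dims),
                                             sigma=sigma_vox, mode="constant")
                bold[j] = sm.ravel()[in_mask]
        nuisance = np.column_stack([
            wm, csf,
            np.concatenate([[0.0], np.diff(wm)]),
            np.concatenate([[0.0], np.diff(csf)]),
        ])
        if noisy:
            n_spikes = int(cfg.high_motion_spike_fraction * t)
        else:
            n_spikes = int(rng.integers(cfg.spikes_per_scan[0],
                                        cfg.spikes_per_scan[1] + 1))
        spike_frames = rng.choice(np.arange(cfg.T_bold // 10, t),
                                  size=n_spikes, replace=False)
        motion = _motion_trace(rng, t, cfg, spike_frames)
        site = cfg.sites[site_counters[group] % len(cfg.sites)]
        site_counters[group] += 1
        scans.append(ParticipantScan(
            participant_id=f"sub-{i:03d}",
            bold=bold.astype(np.float32),
            motion=motion,
            nuisance=nuisance,
            tr_seconds=cfg.tr_seconds,
            age=float(np.round(rng.uniform(6.0, 17.0), 1)),
            sex=str(rng.choice(["M", "F"])),
            site=site,
            group=group,
        ))
    return scans
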