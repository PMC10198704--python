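"""Seeded end-to-end experiments on synthetic data.

These functions wire the generators and pipeline stages into reproducible
experiments: planted-network recovery, shared-hub removal by the specificity
stage, family-wise-error calibration of the two permutation procedures, and
power of the clinical validation GLM. They are used by the test suite, the
acceptance script and the example scripts alike.

Problem sizes: recovery and hub-removal run at the generator's default scale;
the repeated calibration/power simulations use ``SyntheticConfig.small()``
grids and shorter scans so that hundreds of replicates fit in minutes on one
CPU. Only sizes are reduced — noise levels, effect sizes and all analysis
thresholds are the defaults.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .conjunction import conjoin_networks
from .connectome import group_tmaps
from .grid import BinaryMask, dice
from .inference import PermutationScheme, TfceParams
from .mapping import NetworkMapConfig, run_cnm, run_lnm
from .specificity import permutation_fwe, sensitive_and_specific
from .synthetic import (
    GroundTruth,
    SyntheticConfig,
    default_ground_truth,
    make_clinical_cohort,
    make_connectome,
    make_coordinate_studies,
    make_lesion_cohort,
)
from .validation import (
    DenoiseConfig,
    censor_and_screen,
    denoise,
    group_difference_clusters,
    motion_comparison,
    participant_fz_map,
)

__all__ = [
    "child_seeds",
    "recovery_experiment",
    "specificity_experiment",
    "hub_removal_rate",
    "specificity_null_fwer",
    "run_validation_glm",
    "validation_null_fwer",
    "validation_power",
]


def child_seeds(seed: int, n: int) -> np.ndarray:
    """Derive n independent 32-bit child seeds from one master seed."""
    return np.random.SeedSequence(seed).generate_state(n)


# ---------------------------------------------------------------------------
# recovery of the planted network (LNM + CNM + conjunction)
# ---------------------------------------------------------------------------

def recovery_experiment(seed: int, cfg: SyntheticConfig | None = None) -> dict:
    """Run LNM on in-network lesions and CNM on jittered coordinate studies
    against one synthetic connectome; report Dice against the planted network
    and the conjunction of the two sensitivity networks."""
    cfg = cfg or SyntheticConfig()
    truth = default_ground_truth(cfg)
    s = child_seeds(seed, 3)
    conn = make_connectome(cfg, truth, seed=s[0])
    lesions = make_lesion_cohort(truth, cfg, "in_network", seed=s[1])
    studies = make_coordinate_studies(truth, cfg, seed=s[2])
    lnm = run_lnm(conn, lesions)
    cnm = run_cnm(conn, studies)
    conj = conjoin_networks(lnm.sensitive_pos, lnm.sensitive_neg,
                            cnm.sensitive_pos, cnm.sensitive_neg,
                            labels=("lnm", "cnm"))
    contained = (
        np.all(conj.positive.membership <= lnm.sensitive_pos.membership)
        and np.all(conj.positive.membership <= cnm.sensitive_pos.membership)
        and np.all(conj.negative.membership <= lnm.sensitive_neg.membership)
        and np.all(conj.negative.membership <= cnm.sensitive_neg.membership)
    )
    return {
        "truth": truth, "lnm": lnm, "cnm": cnm, "conjunction": conj,
        "dice_lnm_pos": dice(lnm.sensitive_pos, truth.network_mask_pos),
        "dice_lnm_neg": dice(lnm.sensitive_neg, truth.network_mask_neg),
        "dice_cnm_pos": dice(cnm.sensitive_pos, truth.network_mask_pos),
        "dice_cnm_neg": dice(cnm.sensitive_neg, truth.network_mask_neg),
        "conjunction_pos_voxels": conj.positive.size,
        "conjunction_neg_voxels": conj.negative.size,
        "conjunction_contained": bool(contained),
    }


# ---------------------------------------------------------------------------
# specificity: shared-hub removal and null calibration
# ---------------------------------------------------------------------------

def specificity_experiment(seed: int, cfg: SyntheticConfig | None = None,
                           n_perm: int = 100, tfce_steps: int = 50) -> dict:
    """One full sensitivity+specificity run: case lesions in the planted
    network, control lesions at the shared-latent control nodes; reports
    whether the shared hub appears in the sensitivity network and whether the
    specificity restriction removes it while keeping the true target nodes."""
    cfg = cfg or SyntheticConfig()
    truth = default_ground_truth(cfg)
    s = child_seeds(seed, 3)
    conn = make_connectome(cfg, truth, seed=s[0])
    cases = make_lesion_cohort(truth, cfg, "in_network", seed=s[1])
    controls = make_lesion_cohort(truth, cfg, "control_network", seed=s[2])
    lnm = run_lnm(conn, cases)
    control_t = group_tmaps(conn, controls)
    spec = permutation_fwe(
        lnm.per_seed_t, control_t,
        scheme=PermutationScheme(n_perm=n_perm, rng_seed=int(s[0]) % (2**31)),
        params=TfceParams(n_steps=tfce_steps),
        mask=truth.brain_mask,
    )
    snc_pos = sensitive_and_specific(lnm.sensitive_pos, spec.significant_pos)
    snc_neg = sensitive_and_specific(lnm.sensitive_neg, spec.significant_neg)

    def _at(node_role: str, mask: BinaryMask, which: int = 0) -> bool:
        node = truth.nodes_with_role(node_role)[which]
        return bool(mask.membership[truth.grid.world_to_voxel(node.center_mm)])

    return {
        "truth": truth, "lnm": lnm, "specificity": spec,
        "snc_pos": snc_pos, "snc_neg": snc_neg,
        "hub_in_sensitive": _at("hub", lnm.sensitive_pos),
        "hub_in_snc": _at("hub", snc_pos),
        "hub_removed": _at("hub", lnm.sensitive_pos) and not _at("hub", snc_pos),
        "target_in_snc": _at("target", snc_pos),
        "negative_in_snc": _at("negative", snc_neg),
    }


def hub_removal_rate(seed: int, n_runs: int = 20,
                     cfg: SyntheticConfig | None = None,
                     n_perm: int = 100, tfce_steps: int = 50) -> dict:
    """Fraction of seeded runs in which the shared hub is present in the
    sensitivity network but removed by the sensitive-and-specific step."""
    seeds = child_seeds(seed, n_runs)
    removed = in_sensitive = 0
    for s in seeds:
        out = specificity_experiment(int(s), cfg=cfg, n_perm=n_perm,
                                     tfce_steps=tfce_steps)
        in_sensitive += out["hub_in_sensitive"]
        removed += out["hub_removed"]
    return {"n_runs": n_runs, "hub_in_sensitive": in_sensitive,
            "hub_removed": removed, "removal_rate": removed / n_runs}


def specificity_null_fwer(seed: int, n_datasets: int = 100, n_perm: int = 200,
                          n_case: int = 10, n_control: int = 10,
                          cfg: SyntheticConfig | None = None,
                          tfce_steps: int = 32, alpha: float = 0.05) -> dict:
    """Family-wise error calibration of the TFCE permutation test.

    For each null dataset, case and control lesions are drawn from the SAME
    uniform in-brain placement distribution (exchangeable groups); the outcome is
    whether any voxel in either direction is declared significant at alpha.
    The detection fraction should match alpha within Monte-Carlo error.
    """
    cfg = cfg or SyntheticConfig.small(dims=(10, 10, 10), n_subjects=12, T=60)
    truth = default_ground_truth(cfg)
    seeds = child_seeds(seed, 3 * n_datasets).reshape(n_datasets, 3)
    hits = 0
    for s_conn, s_les, s_perm in seeds:
        conn = make_connectome(cfg, truth, seed=s_conn)
        lesions = make_lesion_cohort(truth, cfg, "uniform",
                                     n_lesions=n_case + n_control, seed=s_les)
        t_maps = group_tmaps(conn, lesions)
        spec = permutation_fwe(
            t_maps[:n_case], t_maps[n_case:],
            scheme=PermutationScheme(n_perm=n_perm,
                                     rng_seed=int(s_perm) % (2**31),
                                     alpha=alpha),
            params=TfceParams(n_steps=tfce_steps),
            mask=truth.brain_mask,
        )
        hits += int(spec.significant_pos.size + spec.significant_neg.size > 0)
    return {"n_datasets": n_datasets, "n_hits": hits,
            "fwer": hits / n_datasets, "alpha": alpha}


# ---------------------------------------------------------------------------
# clinical validation: pipeline wrapper, calibration and power
# ---------------------------------------------------------------------------

def scaled_denoise_config(cfg: SyntheticConfig) -> DenoiseConfig:
    """Denoise settings with the volume screen scaled to the configured scan
    length, preserving the default ratio (300 kept of ~376 usable frames)."""
    usable = cfg.T_bold - DenoiseConfig().discard_initial
    return DenoiseConfig(min_volumes=int(round(usable * 300.0 / 376.0)))


def run_validation_glm(truth: GroundTruth, cfg: SyntheticConfig, seed: int,
                       n_perm: int = 200,
                       denoise_cfg: DenoiseConfig | None = None,
                       seed_mask: BinaryMask | None = None) -> dict:
    """Generate a clinical cohort and run the full validation stage: motion
    censoring and screening, denoising, Fisher-z seed maps, covariate GLM
    with permutation cluster-extent FWE, and the group motion comparison."""
    s = child_seeds(seed, 2)
    denoise_cfg = denoise_cfg or scaled_denoise_config(cfg)
    scans = make_clinical_cohort(truth, cfg, seed=s[0])
    seed_mask = seed_mask or truth.network_mask_pos
    fz_rows, cov_rows, fd_means = [], [], {"patient": [], "control": []}
    n_excluded = 0
    for scan in scans:
        censor = censor_and_screen(scan, denoise_cfg)
        if not censor.included:
            n_excluded += 1
            continue
        fd_means[scan.group].append(float(censor.fd[censor.kept_frames].mean()))
        cleaned = denoise(scan, denoise_cfg, censor)
        fz_rows.append(participant_fz_map(cleaned, seed_mask, truth.brain_mask))
        cov_rows.append({"participant_id": scan.participant_id,
                         "group": scan.group, "age": scan.age,
                         "sex": scan.sex, "site": scan.site})
    covariates = pd.DataFrame(cov_rows)
    result = group_difference_clusters(
        np.stack(fz_rows), covariates, truth.grid, truth.brain_mask,
        scheme=PermutationScheme(n_perm=n_perm, rng_seed=int(s[1]) % (2**31)),
    )
    t_motion, p_motion = motion_comparison(fd_means["patient"],
                                           fd_means["control"])
    return {
        "result": result, "covariates": covariates,
        "n_excluded": n_excluded,
        "n_patients": int((covariates["group"] == "patient").sum()),
        "n_controls": int((covariates["group"] == "control").sum()),
        "motion_t": t_motion, "motion_p": p_motion,
    }


def _significant_clusters(result, alpha: float = 0.05):
    return [c for c in result.clusters if c.fwe_p < alpha]


def validation_null_fwer(seed: int, n_datasets: int = 100, n_perm: int = 200,
                         cfg: SyntheticConfig | None = None,
                         alpha: float = 0.05) -> dict:
    """Cluster-extent FWE calibration: the clinical generator with the group
    effect switched off (delta = 0), scored on whether any cluster of either
    sign is declared significant."""
    cfg = cfg or SyntheticConfig.small(
        dims=(10, 10, 10), n_patients=8, n_controls=8, T_bold=100)
    truth = default_ground_truth(cfg, group_effect_delta=0.0)
    seeds = child_seeds(seed, n_datasets)
    hits = 0
    for s in seeds:
        out = run_validation_glm(truth, cfg, int(s), n_perm=n_perm)
        hits += int(len(_significant_clusters(out["result"], alpha)) > 0)
    return {"n_datasets": n_datasets, "n_hits": hits,
            "fwer": hits / n_datasets, "alpha": alpha}


def validation_power(seed: int, n_sims: int = 50, n_perm: int = 200,
                     cfg: SyntheticConfig | None = None,
                     delta: float | None = None, alpha: float = 0.05) -> dict:
    """Recovery of the planted patient coupling deficit.

    A simulation counts as a success when some significant cluster's peak
    voxel lies inside the planted frontal target node. With delta = 0 this
    reduces to the null detection rate.
    """
    cfg = cfg or SyntheticConfig.small(T_bold=240)
    if delta is None:
        truth = default_ground_truth(cfg)
    else:
        truth = default_ground_truth(cfg, group_effect_delta=delta)
    # the planted deficit lives on the *smoothed* frontal loading (the BOLD
    # frames are spatially smoothed), so that is the target region a correct
    # recovery should peak in
    from scipy import ndimage
    w = truth.w_frontal.copy()
    if cfg.bold_smooth_fwhm_mm > 0:
        sigma_vox = (cfg.bold_smooth_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
                     / truth.grid.voxel_size_mm)
        w = ndimage.gaussian_filter(w, sigma=sigma_vox, mode="constant")
    support = w >= 0.05 * w.max()
    seeds = child_seeds(seed, n_sims)
    recovered = any_sig = 0
    for s in seeds:
        out = run_validation_glm(truth, cfg, int(s), n_perm=n_perm)
        sig = _significant_clusters(out["result"], alpha)
        any_sig += int(len(sig) > 0)
        hit = False
        for c in sig:
            peak_idx = truth.grid.world_to_voxel(c.peak_mm)
            if support[peak_idx]:
                hit = True
        recovered += int(hit)
    return {"n_sims": n_sims, "n_recovered": recovered,
            "recovery_rate": recovered / n_sims,
            "any_significant_rate": any_sig / n_sims,
            "delta": truth.group_effect_delta}
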