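# Methods

`ticnet` implements a causal network-mapping workflow for symptom
localisation — developed around tic disorders, but generic over any symptom
with focal-lesion case reports and published patient-versus-control
coordinates. This note records the models, the defaults and why they were
chosen, what the synthetic data do and do not emulate, and the numerical
decisions a maintainer would otherwise have to reverse-engineer.

## Seed-based mapping against a normative connectome

All mapping stages share one statistical core. For a seed region S (a traced
lesion or a combined coordinate seed) and subject s of a normative
resting-state cohort, the seed time course is the unweighted mean BOLD series
over S's in-mask voxels. Its Pearson correlation r_sv with every brain voxel
v is variance-stabilised with the Fisher transform z = atanh(r) (r clipped at
|r| = 1 − 1e−6 so z stays finite at self-correlated voxels), and the group
map is the voxelwise one-sample t across subjects,

    t(v) = mean_s z_sv * sqrt(n) / sd_s(z_sv),   df = n − 1.

The per-voxel statistic is not uniquely pinned down by the field's
descriptions of the technique; subject-r → Fisher-z → one-sample-t is the
standard construction and is what we adopt. Degenerate voxels are handled
explicitly: zero-variance voxel series get r = 0; an exactly zero
across-subject spread with nonzero mean maps to a ±1e6 sentinel (the
degeneracy test is relative, sd ≤ 1e−6·|mean|, so floating-point cancellation
in the accumulating fast path cannot fabricate astronomical t values).

Maps are binarised at |t| ≥ 7 (inclusive), separately for positive and
negative connectivity. With n = 1000 connectome subjects and a ~2.3×10⁵-voxel
mask, the Bonferroni-corrected two-sided p at t = 7 is ≈ 1.1×10⁻⁶, which is
why that particular cut functions as a whole-brain corrected threshold
(`whole_brain_corrected_p`).

**Lesion network mapping (LNM)** overlays the N binarised lesion maps and
keeps voxels reached by at least k_min lesions ("sensitivity network").
**Coordinate network mapping (CNM)** first unions 4-mm spheres at every
coordinate a study reports into one combined seed per study (pooling higher-
and lower-volume coordinates; a direction-stratified mode exists but is off
by default) and then applies the identical composition over studies. k_min
defaults to ⌈0.84·N⌉, reproducing the 16-of-19 and 6-of-7 ratios at their
native cohort sizes while remaining meaningful for other N; it is a config
parameter, not a constant. Lesions and studies are never weighted by volume
or sample size — one seed, one vote.

Grids must match exactly between interacting volumes; resampling
(nearest-neighbour for masks, trilinear for scalar maps) exists but must be
invoked deliberately, because silent interpolation corrupts overlap counts.
Voxel indices are 0-based; coordinate snapping rounds half away from zero in
voxel-index space — a documented choice, since no convention is canonical.

## Specificity: two-group GLM with TFCE permutation FWE

Sensitivity alone cannot distinguish "connected to these lesions" from
"connected to lesions in general". The specificity stage compares the case
seed t-maps against pooled control-disorder t-maps (default: one pooled
control group, mirroring cohorts of 25 + 29 + 36 control lesions; per-group
contrasts are available) with a voxelwise pooled-variance two-sample t, then
enhances it with threshold-free cluster enhancement,

    TFCE(v) = Σ_h e(h, v)^E · h^H · dh,   E = 0.5, H = 2, 26-connectivity,

approximated with 100 equal steps from 0 to the map maximum (a right-endpoint
Riemann sum, converging from above at O(1/steps); an isolated unit-extent
peak of height h integrates to h³/3, which the tests verify to 2% at 1000
steps). Group labels are permuted (exhaustively, with a warning, when the
requested permutation count exceeds the number of distinct relabelings), and
each voxel's FWE-corrected p is

    p(v) = (1 + #{perm max-TFCE ≥ TFCE_obs(v)}) / (n_perm + 1).

The permutation statistic is the maximum TFCE over the mask **and over both
contrast directions**. A per-direction null each tested at α would control
each direction separately but let the two-direction family run at ≈ 2α; the
joint maximum controls the family at α exactly, and the null-simulation
calibration targets exactly that family. "Sensitive and specific" is then the
voxelwise AND of the sensitivity network and the significant voxels, per
direction.

## ALE meta-analysis

Each study's modelled-activation (MA) map places a 3-D Gaussian at every
focus. The kernel width comes from the published two-component empirical
uncertainty model: between-template and between-subject Euclidean
displacements of 5.7 mm and 11.6 mm, converted to per-axis FWHM and combined
as sqrt(f_t² + f_s²/n) — cited constants, not quantities fitted here. Kernels
are normalised to unit mass (probability per voxel); within a study the MA
value is the maximum over focus kernels, so duplicated foci add no evidence.
Across studies, ALE(v) = 1 − Π(1 − MA_i(v)), computed in per-voxel sorted
order so the result is bit-identical under study reordering.

Inference relocates every study's foci uniformly at random within the
analysis mask and recomputes ALE. Because relocation makes voxels
exchangeable, the null ALE values are pooled across voxels and permutations;
this is what makes a cluster-forming threshold of p < 0.001 attainable with a
few hundred permutations (a strictly per-voxel count would floor at
1/(n_perm+1)). Clusters of suprathreshold voxels (26-connectivity) are
corrected by the permutation distribution of the maximum cluster size, whose
p floors at exactly 1/(n_perm+1). Per cluster we report the ALE-weighted
centre of gravity, the peak ALE, and the ALE at the voxel nearest the centre
of gravity — published tables are ambiguous about which ALE value they print,
so both are kept. Higher- and lower-volume coordinate sets are analysed as
separate contrasts by default.

## Conjunction and spatial correlation

The conjunction of two signed networks is the voxelwise AND, positive with
positive and negative with negative, never across signs. Spatial correlation
between two sets of unthresholded t-maps is the Pearson correlation over
in-mask voxels for every cross-set pair; the summary is the inverse Fisher
transform of the mean Fisher-z of the pairwise correlations (the pairwise
matrix is always returned so alternative aggregations can be computed;
correlating group-mean maps is the obvious alternative). Constant maps have
undefined correlations and are excluded with a warning.

## Clinical validation

Inputs are assumed realigned, MNI-normalised, spatially smoothed BOLD
matrices — the heavy preprocessing (registration, ICA-based artefact removal)
belongs to upstream pipelines and is represented here only by the nuisance
interface. The implemented denoising chain, in order: discard the first 4
volumes; censor frames with framewise displacement FD > 0.5 mm, where
FD(t) = Σ|Δtranslations| + 50 mm·Σ|Δrotations| (rotations in radians
projected onto a 50-mm sphere); screen out participants with fewer than 300
remaining volumes (kept at exactly 300); linear detrend; OLS regression of
white-matter and CSF means plus their first derivatives (collinear columns
dropped with a warning); zero-phase frequency-domain band-pass 0.008–0.09 Hz.
Censoring deletes volumes before filtering — the simplest defensible reading
of censor-during-denoising — and the retained frames are filtered as if
contiguous, a known approximation of deletion-based scrubbing.

Group inference: Fisher-z seed maps enter a voxelwise GLM with the group
contrast adjusted for age (centred), sex and site (dummy-coded, first level
dropped; columns that add no rank are dropped with a warning, so single-level
covariates degrade gracefully to a plain two-sample t — the tests exploit
this reduction as an oracle). A site containing only one group triggers a
confounding warning. Clusters form at the two-sided height threshold
|t| ≥ t(1 − 0.001/2, df), separately per sign; cluster-extent FWE p-values
come from a Freedman–Lane permutation (permute the rows of the
nuisance-residualised data, refit the full model) of the maximum cluster size
over both signs. Freedman–Lane was chosen over parametric random-field
cluster correction to keep the stage self-contained, assumption-light and
deterministic under a seed; against a parametric implementation small
numerical differences are expected. Head motion is compared between groups
with a two-sided pooled-variance t-test on mean FD.

## The synthetic world

The generator (`ticnet.synthetic`) is first-class, tested code. Two latent
AR(1) time courses (coefficient 0.4, unit marginal variance) drive a grid of
default size 20×24×20 at 2 mm (≈ 3400 in-brain voxels in an ellipsoidal
mask): a *symptom* latent and a *shared* latent. Ten flat-top loading blobs
(exp(−(d²/2σ²)²), truncated below 0.05) define the structure: three case-
lesion nodes loading both latents (0.7/0.7), two pure symptom-network targets
(1.0), one anticorrelated node (−1.0, emulating negative connectivity to a
cortical cluster), a shared hub (shared latent only), two control-lesion
nodes (shared latent), and a frontal validation target with no connectome
loading. The quartic exponent keeps loadings near their peak across the node
and drops them over a thin shell, so "the planted network" (|loading| ≥ 0.05)
is a well-posed Dice target that does not depend delicately on where the
t = 7 cut lands inside a soft Gaussian tail. Voxel series are
loadings × latents + unit-variance white noise.

Cohort shapes mirror the emulated study: a 40-subject connectome (T = 120),
19 case lesions (spheres of 2–4 mm jittered around the lesion nodes),
25/29/36 control lesions at the control nodes, 7 coordinate studies × 11 foci
(3-mm jitter, 2 decoys each, n drawn from 15–40), and a clinical cohort of
21 patients + 25 controls plus 2 + 2 high-motion participants that the data
screen must reject (TR 0.8 s, 380 volumes). Clinical BOLD adds a frontal
course M = ρ·L_symptom + sqrt(1−ρ²)·independent, with ρ = 0.7 in controls and
ρ·(1 − δ), δ = 0.5, in patients; ρ = 0.7 was fixed by an a-priori power
calculation — band-passing 0.008–0.09 Hz at TR 0.8 keeps ~13% of the
spectrum, collapsing the effective temporal dof to ~40 per scan, and weaker
coupling would make any plausible deficit undetectable at n = 21 + 25.
Frames are spatially smoothed (6 mm FWHM), emulating upstream preprocessing;
without this the cluster-extent null is degenerate (all clusters of size 1)
and the test grossly conservative. WM/CSF artefact courses are mixed into
all voxels (weight 0.3) and supplied as nuisance regressors; motion is a
random walk (0.02 mm / 2×10⁻⁴ rad steps) with injected 0.9-mm one-frame
spikes (1–5 per scan; 40% of frames for the high-motion participants).
Covariates: age ~ U(6, 17), random sex, three sites cycled within group.

What the generator does **not** emulate: realistic BOLD spectra,
physiological noise, scanner drift and artefacts beyond AR(1) + spikes,
motion-correlated signal corruption (motion and BOLD are independent, so
censoring is exercised only as a selection mechanism), between-subject
anatomical variability, and any spatial non-stationarity of noise. Passing
recovery and calibration tests therefore demonstrates the *statistical
machinery* — not that the pipeline would behave identically on real fMRI.

## Problem sizes in tests and experiments

Repeated Monte-Carlo experiments run at reduced scale, chosen so the full
suite fits in minutes on one CPU: FWE calibrations use 10³-voxel grids,
12–16 connectome subjects or 8 + 8 participants, 100 null datasets at 200
permutations; the hub-removal experiment uses 20 full-scale runs at 100
permutations with 50 TFCE steps; power uses the default 21 + 25 cohort on a
12×14×12 grid with 240 volumes and 200 permutations. Only sizes are scaled
(the volume screen scales proportionally with scan length, preserving the
300-of-376 ratio); noise levels, effect sizes, thresholds and all analysis
defaults are never changed between experiments. Calibration is asserted
against the central 95% binomial interval around the nominal 5% — with the
null-rate checks at 100 replicates, since a 50-replicate estimate of a 5%
rate is too noisy to be a meaningful check.

## Known limitations

* The connectome generator does not smooth its BOLD, so normative t-maps are
  spatially rougher than real seed maps; TFCE inference is exercised on
  rough fields (valid, but not identical in power profile to real data).
* ALE voxel p-values use the pooled (stationary) null; near mask edges the
  true per-voxel null is slightly different because kernels are clipped.
* The Freedman–Lane cluster test and the deletion-based scrubbing are
  approximations whose agreement with parametric/spike-regression
  alternatives is documented above but not reproduced numerically.
* `run_cnm` with a single study relaxes k_min to 1 (a single-seed network);
  sensible, but any multi-study threshold semantics do not apply.
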