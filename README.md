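# ticnet

Mapping the brain network behind a symptom from three independent lines of
evidence — and checking that the machinery actually works.

Focal lesions that *cause* a symptom (here: tics) are scattered across the
brain, but they tend to be functionally connected to a common network.
`ticnet` implements the full analysis chain used to localise such a network
and refine it for the idiopathic population (Tourette syndrome):

1. **Lesion network mapping (LNM)** — seed each lesion in a normative
   resting-state connectome, build the group connectivity t-map
   (subject r → Fisher z → one-sample t), binarise at |t| ≥ 7, overlay, and
   keep voxels connected to ≥ k of N lesions (default ⌈0.84·N⌉, i.e. 16/19).
2. **Specificity** — voxelwise two-sample GLM of case versus
   control-disorder seed t-maps with threshold-free cluster enhancement
   (TFCE, E = 0.5, H = 2) and permutation FWE from the max-TFCE null over
   both contrast directions; intersecting with the sensitivity network gives
   the *sensitive and specific* network.
3. **Coordinate network mapping (CNM)** — 4-mm spheres at published
   patient-vs-control coordinates, pooled into one combined seed per study,
   then the same composition over studies (≥ 6/7).
4. **ALE meta-analysis** — sample-size-dependent Gaussian kernels
   (FWHM = √(f_t² + f_s²/n)), per-study max rule, ALE = 1 − Π(1 − MA_i),
   uniform-relocation permutation null, cluster-level FWE.
5. **Conjunction** — voxelwise AND of the signed networks (positive with
   positive, negative with negative), plus spatial correlation between map
   sets.
6. **Clinical validation** — motion censoring (FD > 0.5 mm), volume screen
   (≥ 300), nuisance regression and 0.008–0.09 Hz band-pass, Fisher-z seed
   maps, and a covariate GLM (age, sex, site) with Freedman–Lane
   cluster-extent FWE comparing patients and controls.

Every stage runs on synthetic data with planted ground truth — a miniature
normative connectome with smooth network nodes (including an anticorrelated
node), lesion cohorts, jittered coordinate "studies", and a patient/control
BOLD cohort with a tunable coupling deficit — so recovery, specificity and
error control are testable end to end without any restricted data. The
generator is part of the library (`ticnet.synthetic`), not a test fixture.

Intended users: neuroimaging methods researchers and students who want a
transparent, fully seeded, pure-Python implementation of the LNM/CNM
workflow to study, extend, or validate against.

## Worked example

```bash
python examples/01_lesion_network_mapping.py
```

```
lesions: 19  (sizes 6-31 voxels)
sensitivity threshold: >= 16/19 lesions
positive network: 528 voxels (Dice vs planted network: 0.696)
negative network: 106 voxels (Dice vs planted anticorrelated node: 0.726)
max positive overlap count: 19
```

Nineteen synthetic lesions were placed inside the planted network's nodes;
the pipeline maps each lesion's connectivity, thresholds at |t| ≥ 7 and keeps
voxels connected to at least 16 of 19 lesions. Dice ≈ 0.7 against the planted
support means the sensitivity network recovers the ground-truth network; the
106-voxel negative network is the planted anticorrelated node, found through
its t ≤ −7 connectivity alone.

```bash
python examples/04_group_validation.py
```

```
included after motion screen: 21 patients, 25 controls (4 excluded)
group motion comparison (mean FD): t = 0.15, p = 0.881
GLM df = 40, two-sided height threshold |t| >= 3.55
clusters (size, peak t, peak mm, cluster FWE p):
   262  -11.94  (-3, 15, 3)  0.005  <- significant, 4.3 mm from planted frontal node
     2  +4.32  (1, 13, -13)  0.323
     ...
mean Fz in cluster 1: patients 0.582, controls 0.921
```

The four injected high-motion participants are rejected by the ≥ 300-volume
screen, motion does not differ between the included groups, and the planted
50% patient coupling deficit is recovered as a single FWE-significant
negative cluster at the frontal target node, with lower patient Fisher-z —
the end-to-end behaviour the validation stage exists to detect.

The other examples cover coordinate mapping and ALE
(`02_coordinate_mapping_and_ale.py`) and the specificity/conjunction stages
(`03_specificity_and_conjunction.py`).

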