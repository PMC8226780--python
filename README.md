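# headperturb

How much do head-model inaccuracies corrupt EEG resting-state functional
connectivity? `headperturb` answers that question on a fully synthetic
testbed: it builds a voxelized multi-tissue head phantom, simulates coupled
neural sources organized into resting-state networks (RSNs), solves the EEG
forward problem by finite differences, reconstructs source activity with
eLORETA, measures connectivity with orthogonalized band-limited power
envelope correlations, and then systematically degrades the head model —
electrode positioning errors and head-tissue segmentation errors — to
quantify how each degradation distorts the recovered connectivity.

It is aimed at EEG methods researchers who want a controlled, reproducible
benchmark of source-space connectivity robustness, where ground truth is
known by construction.

## The pipeline in brief

1. **Phantom** — concentric scalp/skull/brain shells on an isotropic voxel
   grid, optionally subdivided into 12 tissue classes (skin, muscle, fat,
   eyes, compact/spongy bone, CSF, cortical/cerebellar grey and white
   matter, brainstem) such that merging them reproduces the 3-shell
   geometry exactly.
2. **Forward model** — the quasi-static potential equation ∇·(σ∇φ) = 0 is
   discretized with a 7-point finite-difference stencil (harmonic-mean face
   conductivities); the leadfield **K** (channels × 3·nodes, µV/nA·m) is
   assembled by reciprocity, one conjugate-gradient solve per electrode. A
   closed-form concentric-spheres Legendre series serves as validation
   oracle (median RDM ≈ 0.06 at 4 mm voxels).
3. **Sources** — each of 21 seeds (6 networks, two of them strictly
   lateralized) emits band-limited noise with a log-normal amplitude
   envelope; envelopes share network-level and global components so that
   the log-envelope correlation is `intra_coupling` within networks and
   `inter_coupling` between them, by construction.
4. **Inverse** — eLORETA: a weighted minimum-norm solution whose node
   weights W_i are iterated as the symmetric square roots of K_iᵀ M K_i,
   giving exact localization of point sources.
5. **Connectivity** — seed time courses → 2 s Hamming STFT (50% overlap) →
   per-bin orthogonalization (imag(Y·conj(X)/|X|)) → log power envelope
   Pearson correlation across windows → Fisher z → band averages (delta
   1–4, theta 4–8, alpha 8–13, beta 13–30, gamma 30–80 Hz).
6. **Perturbation study** — 13 test models per replicate: 8 electrode-error
   montages (systematic rigid rotations vs per-electrode random
   displacements × 0.25/0.5/0.75/1 cm), 2 device presets (3D scan:
   0.25 cm systematic; digitizer: 0.5 cm systematic + 0.25 cm random), and
   3 degraded segmentations (12-layer warped, 3-layer warped, 3-layer
   template with template electrodes). Each model's connectivity matrices
   are compared to the reference workflow by Spearman correlation
   (Fisher-z), followed by main-effects ANOVAs, Tukey-style post-hoc
   comparisons and paired Wilcoxon tests.

## Worked example

```python
from headperturb.study import StudyConfig, run_study

report = run_study(StudyConfig(n_replicates=10, master_seed=0))
print(report.fig6_medians)
```

```
   error_type  magnitude_cm  median_z
0      random          0.25  0.686630
1      random          0.50  0.507462
2      random          0.75  0.397461
3      random          1.00  0.310729
4  systematic          0.25  0.729935
5  systematic          0.50  0.549738
6  systematic          0.75  0.432291
7  systematic          1.00  0.401052
```

Each number is the median (over 10 replicates) Fisher-z Spearman similarity
between a test model's connectivity matrices and the reference ones, so
higher = more robust. The table shows the two key electrode-error effects:
similarity degrades monotonically as the error magnitude grows, and random
per-electrode errors hurt more than systematic rigid rotations once the
displacement reaches 0.5 cm (paired Wilcoxon on the per-replicate z values
is Bonferroni-significant at 0.5–1.0 cm, not at 0.25 cm). The study summary
(`report.qualitative`) additionally shows that degraded tissue
segmentations (median z ≈ 0.34) damage connectivity far more than
electrode-device errors (median z ≈ 0.63), with the 3-layer template model
worst of all.

The same pipeline is scriptable from the shell:

```bash
headperturb simulate  --config study.yaml --out sim/
headperturb run-study --config study.yaml --out report/
```

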