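# Methods

This note documents the models, numerical choices, and limitations of the
`headperturb` pipeline, in the order the data flow through it.

## Head phantom

The head is modeled as concentric spherical shells on an isotropic voxel
grid (default scalp/skull/brain outer radii 92/85/80 mm at 4 mm voxels for
API-level work; the study preset uses thicker 92/82/72 mm shells, see
below). Voxel centers are labeled by their radius; the world frame is RAS
in mm with the origin at the head center, voxel indices 0-based, and a
voxel center exactly at the origin (odd grid dimensions). A volume is
rejected when the thinnest shell spans less than one voxel — a thinner
shell cannot be represented without holes.

The 12-tissue mode subdivides the three shells by deterministic angular and
radial sectors (scalp → skin/muscle/fat/eyes; skull → compact/spongy bone
in radial thirds; intracranial → CSF rind, cortical grey band at 80–94% of
the brain radius, white matter interior, a posterior-inferior cerebellar
cone and a central inferior brainstem cylinder). Because the subdivision is
a pure relabeling within each shell, merging the 12 classes reproduces the
3-shell labeling voxel for voxel — this is tested, and it makes the
12-vs-3-layer comparisons exact rather than approximate.

Default conductivities (S/m): skin 0.43, muscle 0.1, fat 0.04, eyes 1.5,
spongy bone 0.025, compact bone 0.008, CSF 1.79, grey matter 0.33, white
matter 0.14, brainstem 0.33; 3-shell: scalp 0.43, skull 0.0063, brain
0.33. These are configurable literature-style values, not measurements.

## Forward problem

∇·(σ∇φ) = 0 is discretized with the 7-point finite-difference stencil and
harmonic-mean face conductivities — the simplest scheme that is correct for
piecewise-constant isotropic σ. The leadfield is assembled by reciprocity:
for each electrode a unit current is injected against the reference
electrode (first channel), the resulting potential field is solved with
Jacobi-preconditioned conjugate gradients (relative tolerance 1e-8), and
the gain row at each source node is the trilinearly interpolated
central-difference gradient of that field. The singular Poisson system is
grounded at the reference electrode's voxel. A sparse-LU path exists but CG
is roughly two orders of magnitude faster on these systems and is the
default. Degraded segmentations can contain isolated conducting islands;
the solve is restricted to the connected component containing the
reference electrode (physically, injected current cannot reach an island).

Validation is against the classical concentric-spheres solution, computed
per spherical-harmonic order with a 2×2-interface transfer system, radii
scaled by the outer radius for conditioning, and the series truncated
adaptively at a 1e-8 term ratio. Source nodes must keep a 2% radial margin
from the innermost interface (series convergence guard). At 4 mm voxels,
64 electrodes and 50 random nodes the median relative difference measure
(RDM) is ≈ 0.06 (homogeneous sphere: ≈ 0.04), and the median RDM decreases
monotonically over 8 → 6 → 4 mm voxels. Magnitudes carry a systematic
lnMAG offset of ≈ 0.2 for the three-shell case — voxelized thin resistive
shells transmit slightly more current than perfect spherical ones — which
cancels in all similarity analyses (they are scale-free).

## Source simulation

Each of 21 seeds (6 networks: DMN, DAN, SMN, VN bilateral; VAN
right-lateralized, LN left-lateralized; a fixed table of unit directions at
85% of the brain radius, nudged radially into grey matter at coarse
resolutions) emits, per simulated band, unit-variance band-pass filtered
white noise multiplied by a log-normal envelope. The log-envelope of seed
i in network k is σ_l·(√c_inter·g + √(c_intra−c_inter)·s_k +
√(1−c_intra)·p_i), with g, s_k, p_i independent unit-variance Gaussian
processes (Gaussian-smoothed white noise, 0.25 s timescale). The
log-envelope correlation is therefore exactly `intra_coupling` within and
`inter_coupling` between networks in expectation, and this matrix is stored
as the simulation's ground truth. Defaults: intra 0.9, inter 0.1, σ_l =
0.4 (envelope swings of roughly ×1.5, a realistic modulation depth), seed
moment 10 nA·m, radial orientation fixed per node, 300 s at 250 Hz.
Background activity is 1/f noise at 100 randomly chosen non-seed grid nodes
(sparse generators, 20% of seed amplitude). Sensor noise is spatially white
Gaussian, average-referenced, scaled to a requested SNR (default 10 dB)
defined as mean-over-channels signal/noise variance.

What the generator does *not* emulate: cortical geometry and orientation
dispersion, physiological artifacts (EOG/EMG), non-stationarity, and 1/f
structure *within* the coupled bands. Passing tests therefore demonstrate
correctness of the machinery and sensitivity of the comparison logic — not
performance on real recordings.

## Inverse solution

eLORETA: node weights W_i (3×3) iterated as symmetric square roots of
K_iᵀ M K_i, with M the eigendecomposition pseudo-inverse (relative cutoff
1e-12) of Σ_j K_j W_j⁻¹ K_jᵀ + α H, H the average-reference centering
operator. α is expressed as a fraction of the mean diagonal of that
sensor-space matrix; default 0.05, and 0 for the noiseless
exact-localization regime. Iteration stops when the maximum relative
Frobenius change of any W_i falls below 1e-6 (max 100 iterations; weights
are renormalized to mean trace 3 each pass, which does not affect the
kernel). With α → 0 the reconstructed power map peaks at the true node for
every tested point source — the property that distinguishes eLORETA from
other weighted minimum-norm solutions — and this is verified for all nodes
of a small grid and 20 random nodes of the full-pipeline grid.

## Preprocessing

Band-pass: zero-phase (forward-backward) Butterworth, order 4, default
1–80 Hz, channel means removed first. Bad channels can be replaced by
inverse-distance-weighted means of their nearest good neighbors. REST
re-referencing maps average-referenced data toward an infinity reference
through the truncated-SVD (relative cutoff 1e-6) minimum-norm fit of the
average-referenced gain followed by re-expression through the unreferenced
gain. Reciprocity-based solvers only determine the gain up to the injection
reference, so the reference-electrode-referenced gain stands in for the
infinity-referenced one — the practical convention when only a referenced
gain exists; the estimator is idempotent and linear either way. ICA is
deliberately absent: the synthetic data carry no artifacts.

## Connectivity

STFT with 2 s Hamming windows, 50% overlap (0.5 Hz bins; a 300 s series
gives 299 windows); each segment is demeaned before tapering. Seed ROI time
courses are the dominant-orientation projections (first singular vector) of
all grid-node moments within the 6 mm ROI radius, sign-fixed by an
intrinsic convention (largest-magnitude sample positive) so a global
polarity flip of the sources changes nothing. For each bin and seed pair,
the zero-lag (leakage) component is removed by orthogonalization —
imag(Y·conj(X)/|X|) — log power envelopes (ε = 1e-12 × median power) are
Pearson-correlated across windows, both orthogonalization directions are
averaged (making the matrix symmetric by construction), Fisher-z
transformed, and z values are averaged over the bins of each half-open band
[lo, hi). Envelopes are correlated per bin and then band-averaged, matching
the order of the workflow the estimator comes from. Note that single-bin,
single-window power estimates carry chi-squared sampling noise, which
attenuates measured z well below the generating envelope correlation
(intra-coupling 0.9 yields network-mean z ≈ 0.11 at 300 s); the attenuation
is uniform across pairs, so all rank-based comparisons are unaffected.

## Perturbation study

Test models change exactly one component of the reference workflow
(12-tissue segmentation + reference montage + grey-matter grid):

- *Systematic* electrode error: one rigid rotation of the whole montage
  about a randomly chosen signed head axis (anteroposterior, mediolateral
  or longitudinal), with the angle calibrated so the mean pre-projection
  chord displacement equals the requested magnitude exactly
  (θ = 2·arcsin(d/2ρ̄), ρ̄ = mean distance from the rotation axis).
- *Random* electrode error: an independent rotation per electrode toward a
  uniformly random tangential direction, each with chord displacement
  exactly equal to the magnitude.
- Device presets: 3D scan = 0.25 cm systematic only; digitizer = 0.5 cm
  systematic + 0.25 cm random. Directions are redrawn per replicate.
- Segmentation variants: the 12-tissue labels are resampled through a
  smooth random displacement field (Gaussian-filtered vector noise at 15 mm
  smoothness, RMS amplitude 4 mm in the study preset — about half a study
  voxel, producing tissue Dice degradation comparable to template-warped
  segmentations; a sub-voxel warp would resample to the identity and
  emulate no error at all). "12-layer" keeps all classes, "3-layer" merges
  them, both keep the reference electrodes; "3-layer template" additionally
  re-projects the unperturbed electrode lattice onto the distorted scalp
  (template electrode positions).

All perturbed montages are re-projected onto the scalp, mirroring the
reference workflow's projection step; displacement calibration is defined
pre-projection.

Per replicate, the same simulated recording is analyzed by the reference
workflow and by each of the 13 test workflows (only the perturbed component
is rebuilt); similarity is Spearman's rank correlation between test and
reference connectivity matrices over off-diagonal seed pairs (whole-matrix,
and per network over all pairs involving that network's seeds),
Fisher-transformed. The four-way ANOVA (network × band × magnitude × type)
and three-way ANOVA (network × band × segmentation method) are
main-effects-only fixed-effects decompositions on one z per design cell
(the replicate mean) — 240 and 90 observations, residual dfs 226 and 78 —
with per-replicate values feeding the paired Wilcoxon comparisons instead.
The Wilcoxon signed-rank kernel drops zero differences, uses the exact
dynamic-programming null for n ≤ 25 (tie-aware, average ranks) and a
continuity-corrected normal approximation above; post-hoc marginal-means
comparisons use the studentized-range distribution with the factorial
residual mean square. Randomness: a single master seed fans out through
`numpy.random.SeedSequence` to per-replicate, per-model child seeds (all
below 2³¹).

## Study preset and problem sizes

The default `StudyConfig` is sized for a single CPU: 92/82/72 mm shells at
8 mm voxels, 32 electrodes (120° coverage cap), 8 mm grey-matter grid with
seeds snapped to grid nodes, 60 s of alpha-band-coupled activity at 200 Hz
per replicate, 10 replicates — 131 finite-difference leadfields and
eLORETA solutions in ≈ 4 minutes. Forward-accuracy and localization checks
run at 4 mm voxels with 64 electrodes. These sizes are the package's
defaults, chosen to keep a full study interactive; all of them are
configurable upward.

## Findings on synthetic data, and one that does not transfer

With the default preset the study reproduces three qualitative effects:
median similarity decreases monotonically with electrode-error magnitude;
random errors damage connectivity at least as much as systematic ones from
0.5 cm upward (the paired Wilcoxon is Bonferroni-significant at 0.5–1.0 cm
and not at 0.25 cm); and segmentation degradation hurts far more than
either electrode-device preset, with the 3-layer template model worst.

The fourth effect reported for real heads — strongly lateralized networks
(VAN, LN) being *less* robust than bilateral ones — does **not** emerge on
this phantom: the computed flag and medians are reported by the study
driver, and here the lateralized networks come out slightly more robust.
The mechanism proposed for real anatomy (few nodes concentrated in one
hemisphere near air–tissue interfaces that distort the field) has no
counterpart in a spherically symmetric phantom, so its absence is expected
rather than a defect; treating it as such would require an anatomically
asymmetric phantom, which is outside this package's scope.

## Known limitations

- Spherical geometry only; no realistic cortical surfaces or MNI-space
  seed coordinates (the layout is parametric).
- Isotropic conductivities; the 7-point stencil rather than higher-order
  18/19-point schemes.
- The EDF exporter is a minimal 16-bit writer (1 s records, integer
  sampling rates) meant for interoperability, not archival fidelity.
- Absolute connectivity z values depend on the envelope estimator's
  attenuation and should only be compared within the pipeline.
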