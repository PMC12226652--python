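# Methods

This note documents the models behind `phantomrad`: what the synthetic
phantom and scanner surrogates do and do not emulate, the exact feature and
statistic definitions, the numerical choices, and the limitations a user
should keep in mind when interpreting results.

## Study design

One texture phantom is imaged under a reference protocol and twelve
single-factor variants (13 protocols total). From every protocol image, one
cylindrical ROI per material (28 materials) yields a 93-feature radiomics
vector, giving a 13 × 28 × 93 feature table. Robustness is then quantified
per feature:

- **reproducibility** between the reference and each variant: ICC(A,1) and
  Lin's CCC over the 28 materials (n = 28 subjects, k = 2 protocols);
- **variability** per factor: CV and QCD of each (feature, material) value
  pair, aggregated over materials; and per material: CV and QCD of each
  feature's 13 protocol values.

Bin percentages are always out of 93 features, reported to one decimal,
with an explicit `undefined` bin for zero-denominator cases rather than
silent exclusion.

## The synthetic phantom

Each insert is a cylinder filled with a stationary random texture defined
by a mean attenuation (HU), a marginal SD (HU) and a correlation length
(mm, the sigma of the Gaussian smoothing kernel applied to white noise).
The generated field is renormalized so its sample mean and SD match the
declared values exactly. Texture families add qualitative structure:
granular materials are isotropic Gaussian fields; fibrous ones (the woods)
are anisotropic, elongated along z; porous ones (sponges, soil) pass the
field through a tanh saturation that produces plateau-like pores; water is
exactly uniform at 0 HU. The background is uniform foam at −800 HU.

The 28 default materials span roughly −850 HU (microporous sponge) to
+1100 HU (sand) with texture SDs of 0–130 HU and correlation lengths of
0.8–3.5 mm. These parameters are package defaults declared in
`phantomrad.phantom`, chosen once to be physically plausible for the named
household materials; they are configurable, and no claim is made that they
match any particular physical phantom's values.

Inserts sit on concentric rings (1 + 8 + 9 + 10) sized so that the whole
arrangement fits both the 400 mm standard FOV and the 350 mm high-pitch
FOV. The ground truth is rasterized once per study seed on a fine isotropic
grid (0.25 mm default — strictly finer than every protocol grid, so both
the 1.0 mm and 0.4 mm reconstructions downsample from the same truth) and
shared by all protocols, mirroring a phantom that is physically unchanged
between scans.

## The acquisition surrogate

The scanner chain (photon-counting detection, 70 keV virtual monochromatic
synthesis, vendor iterative reconstruction, reconstruction kernels) is
replaced by image-domain operations whose *statistical* effects are
declared and independently controllable. In order:

1. **Rigid repositioning** (reposition protocol only; default translation
   (3, −2, 1) mm, 2° in-plane rotation) is folded into the resampling step
   by pulling output voxel centres back through the inverse transform.
2. **Tube voltage** (140 kVp): per-material multiplicative contrast factors
   near 1 (default ±3%, deterministic per label). 70 keV virtual
   monochromatic images are nearly kVp-invariant, so the effect is small by
   design; noise targets are unchanged.
3. **Resampling** to the protocol grid (in-plane pitch FOV/matrix, axial
   pitch = slice thickness): Gaussian anti-alias blur matched to the
   downsampling ratio (sigma = 0.42 × ratio, approximating averaging over
   the output voxel) followed by trilinear interpolation.
4. **Kernel PSF**: in-plane Gaussian blur with FWHM 1.2 / 0.9 / 0.7 px for
   Qr40 / Qr44 / Qr48 (sharper kernel = narrower PSF).
5. **Noise**: a correlated Gaussian field added with SD
   σ = σ_ref · √(CTDI_ref/CTDI) · √(t_ref/t) · m_pitch · a_kernel · f_QIR,
   with σ_ref = 10 HU at 10 mGy / 1.0 mm / Qr40, m_pitch = 1.15 for
   high-pitch scans, kernel noise amplification a = 1.0 / 1.35 / 1.8, and
   QIR reduction f = 1.0 / 0.7 / 0.45 at levels 0 / 2 / 4. This is the
   standard quantum-noise scaling; it makes the dose ladder's effect
   monotone by construction. The field is white noise smoothed in-plane
   (base correlation 0.6 px, widened with QIR level, since denoising removes
   high frequencies) and rescaled so the *final* image noise SD equals the
   target exactly. The QIR surrogate therefore acts on the noise component
   only — the signal is untouched, which realizes "edge-preserving
   denoising" in the strongest possible sense and keeps the declared noise
   law exact and testable.

Determinism: every operation is a pure function of (inputs, seed); a study
uses one master seed, from which the ground-truth seed and one child seed
per protocol are spawned.

### ROI geometry

ROIs are disks of a fixed *pixel* diameter (35 px default), so their
physical size follows the pixel pitch: ≈ 27.3 mm on the 400 mm grid and
≈ 23.9 mm on the 350 mm high-pitch grid. Centres are the insert centres
snapped to the reference-protocol pixel lattice (emulating manual placement
on the reference scan) and carried through the scan's rigid transform, so
ROIs track a repositioned phantom exactly; the disk is replicated over the
middle 25 slices (default) regardless of slice thickness, so the 0.4 mm
protocol's ROI covers a thinner physical slab — a deliberate consequence of
copying ROI geometry in voxel units.

## Feature definitions

The 93 features follow the reference radiomics definitions: 18 first-order,
24 gray-level co-occurrence (GLCM), 16 run-length (GLRLM), 16 size-zone
(GLSZM), 14 dependence (GLDM) and 5 neighbourhood gray-tone difference
(NGTDM) features. First-order features use raw HU (Entropy and Uniformity
use the binned histogram); all texture families use fixed-bin-width
discretization, level = ⌊(x − min)/w⌋ + 1 with w = 25 HU default, whose
moving minimum makes texture features invariant to adding a constant to all
HU values. Texture matrices are computed in 3D: GLCM and GLRLM per
direction over the 13 unique neighbour directions with features averaged
over directions; GLSZM zones are 26-connected components of equal level;
GLDM dependence counts neighbours within Chebyshev distance 1 whose level
differs by at most α = 0 (matrix column = dependence + 1); NGTDM uses the
26-neighbourhood mean. A per-slice 2D mode (4 directions, 8-connectivity)
is available but not used by the default study. No resampling,
normalization or filtering precedes extraction, and no shape features are
computed (ROI geometry is fixed by design, so shape carries no
information). The extraction settings are package defaults, declared in
`ExtractionSettings` and hashed into the feature table's provenance.

Degenerate-value policy (e.g. a constant ROI): first-order Skewness and
Kurtosis are returned as 0, GLCM Correlation as 1, and NGTDM Coarseness is
capped at 10⁶ when its denominator vanishes; each such value carries a
degeneracy flag so downstream statistics can count them.

A note on zone connectivity: under 26-connectivity a two-level 3D
checkerboard does *not* decompose into single-voxel zones — the diagonal
neighbours of each voxel share its level, so the two parity classes form
two large zones. The test suite asserts this (verified against a BFS
oracle) and uses an 8-level interleave as the genuine singleton-zone case.

## Statistics

- **ICC(A,1)**: two-way, absolute-agreement, single-measurement form,
  (MS_R − MS_E) / (MS_R + (k−1)MS_E + (k/n)(MS_C − MS_E)) from the two-way
  ANOVA mean squares. Chosen because the protocols are fixed conditions and
  absolute agreement parallels CCC. A design with no variance at all is
  defined as ICC = 1 with a degeneracy flag. Cross-checked against
  pingouin's ICC2 in the tests.
- **CCC**: Lin's original moment form with denominator n (not n − 1); the
  choice matters at n = 28 and is therefore documented.
- **CV** = 100 · SD(n−1) / |mean|; **QCD** = 100 · (Q3 − Q1) / |Q3 + Q1|
  with linear-interpolation (type-7) quantiles — at n = 13 the quantile
  convention changes QCD, hence it is pinned. Absolute values are used in
  the denominators because several features (mean HU, cluster shade) are
  legitimately negative; a zero denominator yields an undefined flag.
- **Bins**: reliability poor [−1, 0.50), moderate [0.50, 0.75), good
  [0.75, 0.90), excellent [0.90, 1]; variability acceptable [0, 10),
  moderate [10, 20), inadequate [20, ∞). The half-open [10, 20) band
  resolves the ambiguity of quoting "10%" vs "11%" as the lower edge.

Per-factor CV/QCD pooling: the bin percentages use per-feature values
(mean over the 28 materials by default; median available), while the
mean ± SD and median (IQR) summary rows use the pooled feature × material
list. The pooling rule is configurable because different published tables
are consistent with different choices.

## Problem sizes

The full-scale configuration (400 mm FOV, 512 matrix, 0.25 mm truth grid
→ 1600 × 1600 × 128 voxels) is the declared study condition and is used for
all structural checks (28 labelled materials, 35 px × 25 layer ROIs).
Replicate-based analyses use `StudyConfig.compact()`: the phantom scaled to
100 mm FOV / 128 matrix with *identical* pixel pitches (0.781 mm standard,
0.684 mm high-pitch) and slice thicknesses, 8 mm inserts, 9 px ROIs over 7
layers. Because every voxel pitch and all surrogate parameters are
unchanged, resampling, PSF and noise effects per voxel are preserved; only
the ROI sample size per feature shrinks. The acceptance script runs 20
compact replicates for the per-factor medians and 50 replicates of a
homogeneous-cube simulation for the noise law.

## What the simulation shows — and what it cannot

Passing tests demonstrate that the *pipeline* behaves lawfully: the noise
ladder produces the declared SD scaling (measured ratio ≈ √(10/0.47)
within sampling error), duplicated protocols give ICC = CCC = 1 and
CV = QCD = 0, and the qualitative ordering of perturbations emerges from
the simulation rather than being coded in: over 20 replicates, median
per-feature ICC is highest for repositioning and tube-voltage change,
lower for high-pitch and the lowest doses, and monotone along the dose
ladder.

The surrogates are phenomenological. Not modelled: projection-domain
physics, spectral bins, beam hardening, scatter, helical sampling
artifacts, vendor iterative-reconstruction nonlinearity, or z-direction
PSF differences between scan modes. Consequently the *magnitude* of the
high-pitch and thin-slice degradations is smaller here than physical
phantom studies report — in this simulation their effect reduces to voxel
geometry changes plus a modest noise multiplier, which lowers median ICC to
roughly 0.77–0.89 rather than below 0.5, and the lowest-dose protocol
(0.47 mGy) can fall below high-pitch in the ordering. Conclusions about
*which physical mechanisms* dominate protocol sensitivity on a real
scanner cannot be read off these numbers; what the package supports is the
study machinery — feature definitions, agreement statistics, summary
layout — and controlled experiments on how feature families respond to
declared, isolated perturbations.

Other known limitations: the material parameters are invented defaults;
ROI sizes in the compact configuration (≈ 450 voxels) make zone- and
run-based features noisier than at full scale; and CV/QCD on two-value
pairs (the per-factor variability) are highly dispersed statistics whose
aggregation rule materially affects summary rows.
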