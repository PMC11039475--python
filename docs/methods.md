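# Methods

`infarct3d` reimplements, as a seeded and testable pipeline, a multiscale
quantitative analysis of bile infarcts (fields of necrotic hepatocytes under
obstructive cholestasis) in 3D X-ray phase-contrast CT of mouse liver. The
original raw volumes are not publicly deposited, so every claim the package
makes is validated by *parameter recovery*: a synthetic-liver generator
plants lesions with known properties, the measurement chain re-estimates
those properties, and the estimates must come back within sampling error of
what was planted. This note records the models, the defaults and why, and
what such validation does and does not establish.

## The synthetic liver

**Two scales.** Mirroring the two acquisitions (3.25 µm pixels for intact
lobes, 0.65 µm for excised sub-volumes), phantoms come in a *lobe* flavour
(vessel trees + infarcts; sinusoids and microchannels are sub-resolution
and omitted) and a *submicron* flavour (a miniature lobule region with a
central-vein trunk, corner portal tracts, a radial sinusoid network,
infarcts and infarct–sinusoidal microchannels). Grids default to 128³
(lobe) and 160³ (submicron) — large enough to hold the full day-7 lesion
load at realistic spacing, small enough that a five-seed replicate of the
whole pipeline runs in minutes on one CPU.

**Vessels.** Hepatic anatomy places terminal hepatic (central) venules at
lobule centres and portal tracts at lobule corners. The generator uses
exactly that: a jittered square lattice (period 48 voxels ≈ 156 µm at lobe
scale) with central trunks at cell centres and portal trunks at cell
corners, each trunk carrying randomly placed, tapering side branches two
generations deep. A deterministic lattice rather than a free-growing random
tree was chosen because the distance-based zonation model needs every
tissue voxel within a bounded distance of both systems, and the lattice
guarantees it by construction (worst case ≈ half a lattice diagonal).
Distinct systems are kept at least one voxel apart so that seeded region
growing between equal-intensity lumina cannot leak from one system into
the other.

**Lesions.** Infarcts are spheres perturbed by random spherical harmonics
of degree 3–6 whose amplitude (the `sphericity_roughness` preset) grows
with post-ligation day, reproducing the observed decline in lesion
sphericity. Degrees 2–3 were rejected: at day-7 amplitude they carve deep
lobes that are geometrically indistinguishable from fused lesion pairs,
whereas the higher degrees give the intended "uneven margin" without
creating false cores. A preset fraction of lesion units is generated as
clusters of 2–3 overlapping blobs (centre separation uniform in 1.75–1.95
× mean radius, verified 26-connected) modelling confluent growth; distinct
units are kept from touching so segmentation components map one-to-one to
generated units. Lesion centres are drawn zone-by-zone with day-dependent
weights; no lesion voxel may fall inside a vascular lumen, and total
lesion load is capped at 40 % of the parenchyma.

**Calibration of the day presets.** Published group statistics anchor the
schedule: confluent fractions 8 / 15 / 21 / 25 % and channel-count means
1.86 / 2.47 / 3.38 / 5.47 for days 1 / 3 / 5 / 7; channel calibre 3.41 µm;
total lesion volume rising ninefold from day 1 to day 7 with a near-linear
rise in lesion number. Per-lobe lesion *counts* are only shown as bar
graphs in the source material, so the preset counts 10 / 20 / 30 / 40 are
order-of-magnitude choices; radii are uniform on [a, 1.5a] µm with a =
12 / 11.68 / 12.72 / 14.53, calibrated by Monte-Carlo of the generator
itself (the expected volume of a lesion *unit* also carries the extra
blobs of fused clusters and the roughness inflation, not just the mean
sphere volume) so the *expected generated* total-volume multipliers
follow 9^((day−1)/6) — ninefold at day 7. Later days gain volume mainly
through lesion count, confluence and roughness, leaving the radius
schedule nearly flat, in line with the flat early growth of single
lesions. Zone
weights move from (0.60, 0.25, 0.15) at day 1 to (0.25, 0.30, 0.45) at
day 7, encoding the periportal-onset → pericentral-dominance reversal.
Microchannel counts per lesion component are Poisson with the day mean
(nonnegative support, not zero-truncated — zero-truncation would bias the
mean above the published values); channels are straight tubes from a
lesion surface point to the nearest sinusoid, requiring a tissue gap of
2–30 voxels, mutually separated exit points, and a verified bridge between
lesion and sinusoid after rasterization.

**Rendering.** Each tissue class maps to a gray level (parenchyma 0.60,
infarct 0.35, sinusoid 0.18, portal/central 0.12, channel 0.08, arbitrary
units) plus Gaussian noise of SD 0.02 — 8 % of the infarct/parenchyma gap,
a deliberately benign noise floor: segmentation accuracy claims hold *for
data of this contrast quality*, which phase-retrieved synchrotron data
approaches but laboratory CT may not.

**What the generator does not emulate.** Partial-volume blur at class
boundaries, intensity inhomogeneity across the lobe, ring and motion
artifacts, anisotropic lesion growth along vessels, real vascular
tortuosity, and any biochemistry of necrosis. Recovery results therefore
demonstrate that the *measurement chain* is unbiased and correctly
implemented — not that it would meet the same error bars on arbitrary real
data.

## Phase-contrast CT simulator and reconstruction

The forward model is parallel-beam and per-projection: line integrals of
the refractive-index decrement δ and attenuation index β (n = 1 − δ + iβ)
build the complex transmission exp(iφ − (2π/λ)∫β ds) with φ =
−(2π/λ)∫δ ds; the wave propagates to the detector by the paraxial Fresnel
kernel exp(−iπλD|f|²); intensity is blurred by a 1-pixel-FWHM Gaussian
detector PSF, modulated by a smooth illumination profile, offset by a dark
level and optionally Poisson-sampled (default 20 000 photons/pixel in the
flat beam). Flat and dark frames are emitted alongside (10 and 5 per
acquisition). Geometry presets follow the two experimental configurations:
16 keV / 28 cm / 3.25 µm / 1200 angles and 14 keV / 16 cm / 0.65 µm / 900
angles over 180°.

Reconstruction inverts the chain: (raw − dark)/(flat − dark) correction
with neighbour-median fill of dead pixels; single-distance
phase–attenuation duality retrieval — divide the frame spectrum by
1 + πλD(δ/β)|f|², take −log — valid for a single material with
proportional δ and β; then slice-wise filtered back-projection. The
projector was matched exactly to `skimage.transform.radon`'s geometry
(rotation by −θ about (n//2, n//2)), so `iradon` is a consistent inverse,
and the output is scaled to an attenuation coefficient μ = 4πβ/λ per µm.

**Validity domain, stated plainly.** The duality filter inverts the
*linearized* near-field contrast, so it is exact only while the phase
varies slowly over the first-fringe scale √(λD) ≈ 4.7 µm. At soft-tissue
δ ≈ 7×10⁻⁷ and 16 keV a 200 µm tissue path accumulates only ≈1.2 rad, and
a smooth-edged single-material blob at that δ round-trips with > 0.999
volume correlation and < 1 % interior RMS at 64–128³; the weak-object
limit is exact to float precision. Voxel-sharp high-contrast rims (e.g. a
binary tissue/air edge) still generate nonlinear fringe residuals
confined to the boundary, as they do on real beamlines. The δ/β ratio is
fixed at 2000, within the "δ up to three orders of magnitude larger than
β" regime that motivates phase contrast for soft tissue. Detectability
experiments embed spheres of 30 % density contrast (necrotic tissue is
less dense) in the tissue background; the simulated chain at 240 angles
and default noise recovers all sphere sizes down to the 2-voxel (6.5 µm)
rung of the ladder — comfortably inside the ≈10 µm smallest
distinguishable lesion reported for the real system, whose raw data
carry artifacts the simulator does not model.

## Segmentation

Infarcts: global dark-threshold. The automatic mode applies Otsu
clustering to non-vessel voxels but accepts the cut only when it looks
like a genuine two-class split (between-class mean separation ≥ 4× the
pooled within-class SD, dark fraction ≤ 45 %); otherwise it falls back to
a robust outlier rule, median − 4×1.4826·MAD. Pure Otsu is a known failure
at low lesion prevalence — on day-1 phantoms (0.3 % lesion voxels) it
splits the parenchyma mode itself and returns Dice 0.008; the guarded
version recovers Dice > 0.99 across all days.

Vessels: seeded breadth-first region growing accepting 26-neighbours
within `grow_tolerance` of the running region mean, waves processed in
ascending (z, y, x) order for determinism, first-claim-wins between
labels. One seed per connected vessel piece (the pipeline takes the EDT
maximum of each piece) stands in for the manual per-vessel seed placement
of the original workflow.

Components: `scipy.ndimage` labeling under configurable 6/18/26
connectivity, physical size filter defaulting to the volume of a 10 µm
sphere (the resolution floor of the lobe-scale images), labels reassigned
1-based in descending volume order.

## Zonation

The 3D hepatic-acinus model partitions parenchyma into three equal-volume
zones by distance to the central-vein tree: thresholding the Euclidean
distance transform at r is identical to dilating the tree by a Euclidean
ball of radius r ("sphere dilation"), and the two radii (r3, r2) are set
by rank so zones III / II / I each hold one third of the parenchyma.
Voxels tied exactly at a threshold are assigned in deterministic
(distance, z, y, x) order, making the equal-volume condition achievable to
one voxel (tolerance default 0.5 % of parenchyma volume). The portal tree
is excluded from all zones but does not enter the distance field — the
construction grows from the central veins only and labels the periportal
remainder zone I. A geodesic (within-parenchyma shortest path) metric is
available for strongly non-convex tissue at small grid sizes; on convex
domains it agrees with the Euclidean default. A lesion spanning several
zones takes the zone holding the largest share of its volume, excluded
voxels leaving the denominator, exact ties resolved to the lower zone
index.

## Morphometry

**Volume and sphericity.** V is the voxel count times voxel volume. The
surface A is a triangulated 0.5-isosurface computed after 2× supersampling
and a Gaussian at the discretization scale (σ = 1.2 upsampled voxels);
raw marching cubes on a binary mask carries ~8 % staircase area inflation,
which would push the sphericity Ψ = π^{1/3}(6V)^{2/3}/A of a true ball to
0.92. With the anti-aliased surface, Ψ(ball) = 0.97–0.99 for radii 12–20
voxels, Ψ(cube) is within 4 % of (π/6)^{1/3}, and Ψ is exactly
scale-invariant. Components touching the grid border are measured but
flagged, and excluded from sphericity distributions (truncated surfaces).

**Confluence.** The individual-vs-confluent call — visual in the original
workflow — is operationalized as: upsample the component crop 2×, take the
interior Euclidean distance transform, find h-maxima cores (h = 0.75
original voxels) and grow them by watershed on the negated distance; the
component is confluent iff ≥ 2 cores hold at least 10 % of its volume
each. The defaults were calibrated on generator truth across all day
presets (accuracy 93–96 % on days 1 and 7; an h of 2 voxels without
upsampling, the first candidate, missed most day-7 fusions because
lobe-scale lesions are only 4–7 voxels in radius and their necks are
sub-voxel features). Raising `min_core_fraction` can only demote a
component to individual, never promote it.

**Microchannels.** The channel lumen mask (dark voxels outside lesions,
sinusoids, and — important in practice — the macro-vessel lumina passed as
`exclude_mask`) is restricted to a 25 µm shell around each lesion; a
channel is a connected lumen piece whose voxels abut both the lesion and a
sinusoid. Counting lumen components rather than skeleton paths is
deliberate: skeletons retract from open tube ends by about one radius and
lose contact for channels only a few voxels long. Calibre is twice the
distance from skeleton voxels to the nearest *tissue* voxel — the mouths
where the lumen opens into lesion or sinusoid are treated as free space —
averaged along the channel (the minimum is reported separately); on
randomly oriented digital cylinders at the 3.41 µm / 0.65 µm-voxel working
point the estimator reads 3.06 ± 0.10 µm, within half a voxel of truth.
Channels thinner than two voxels are flagged unreliable.

## Statistics

Group comparisons reproduce the two-branch scheme: Shapiro–Wilk on both
samples; if both pass at α = 0.05, an independent-samples t test (Welch
variant — the source material says only "independent sample t tests", and
unequal variances are the safer default) with mean ± SD descriptives;
otherwise Mann–Whitney U with median (IQR). A constant sample is routed to
the nonparametric branch. The composite procedure holds its nominal size:
empirical type-I error 0.047–0.050 at n = 6 over 5000 null pairs. No
multiple-testing correction is applied by default, matching the original
reporting; Benjamini–Hochberg is available.

## Problem sizes used in validation

Recovery experiments run at 128³ (lobe) and 160³ (submicron) grids with
five seed replicates, 25 lesions per submicron phantom, 240–400 projection
angles, and ten seeds for the detectability ladder — sizes chosen so the
full validation executes in a few minutes on a single CPU while keeping
every per-target sampling SE small against its acceptance band (e.g.
channel-count SE ≈ 0.2 at a mean of 5.5 over 125 lesions).

## Known limitations

- Recovery accuracy is demonstrated on phantoms with crisp class
  intensities; heavy partial-volume mixing or artifacts would degrade the
  threshold segmentation first.
- The in-situ calibre of *short* detected channels is biased low by a
  voxel or so (few skeleton samples, junction effects); the reported
  3.41 µm-tube working-point accuracy holds for tubes a few diameters
  long.
- The CT simulator is parallel-beam, single-distance, monochromatic; no
  ring/motion artifacts, no multi-distance holotomography.
- The zonation model is the literal distance construction; if the original
  sphere-dilation implementation used anisotropic structuring elements,
  thresholds could differ (its parameters are not published).
- Confluence classification is a geometric surrogate for a visual call;
  its 93–96 % truth accuracy is against *this generator's* notion of
  fusion.
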