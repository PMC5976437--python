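# Methods

## Scientific setting

During early mitosis the pericentriolar material (PCM) expands rapidly:
within ~30 minutes the centrosome must roughly double its content of very
large scaffold proteins such as pericentrin (PCNT, 3336 aa in human).
Because translation elongation runs at only ~3–10 aa/s, a full-length
PCNT takes ~10–20 min to synthesize — a kinetic argument for making the
protein *at* the centrosome rather than importing finished molecules.
Single-molecule FISH (smFISH) shows PCNT mRNA concentrated around the
spindle poles, and an epitope trick — N-terminus immunofluorescence
positive, C-terminus negative, smFISH positive — identifies polysomes
whose nascent chains have an N-terminus but no C-terminus yet, i.e.
active translation sites.

`centrofish` implements the quantification behind these observations as a
reusable pipeline:

1. **Spot detection** of diffraction-limited smFISH signals in 3D,
2. **PCM segmentation** on a reference (anti-PCNT) channel,
3. **Radial statistics**: intensity-weighted fraction of mRNA per 0.5 µm
   distance bin from the nearest centrosome, per cell, averaged across
   cells with 95% CIs,
4. **Translation-site calling** via the N⁺/C⁻ epitope logic inside a
   1–3 µm shell around the centrosome center,
5. **Condition comparisons** (fold change, percent change, two-sided
   unpaired t-tests) of centrosomal intensity, mRNA count, proximal mRNA
   fraction, and shell translation fraction,
6. a **ground-truthed synthetic image generator** whose presets encode
   the biology's reported effect sizes, so every stage is verifiable.

## Synthetic image model

Each synthetic cell is an ellipsoidal mask inside a
(32, 128, 128)-voxel stack at (0.30, 0.12, 0.12) µm/voxel — a
9.6 × 15.4 × 15.4 µm crop around the spindle region. Channels: `mrna`,
`nterm`, `cterm`, `reference`.

**Point sources.** Spot positions are continuous (µm). Rendering
integrates an anisotropic Gaussian PSF (σ = 0.6/0.25/0.25 µm, z/y/x)
exactly over each voxel box (separable erf products), so a source's voxel
sum equals its flux whenever its support is interior — the basis of the
flux-conservation test and of sub-voxel localization tests. No
deconvolution is simulated or implemented.

**Radial law.** A fraction `proximal_fraction` of spots belongs to a
centrosome-proximal component whose *spatial* density decays
exponentially with distance r from a randomly chosen pole; the distance
law is therefore the 3D exponential shell pdf ∝ r² exp(−r/λ), truncated
at 5 µm, with λ = 1.5 µm by default. The shell form (rather than an
exponential distance pdf) keeps the spatial density finite at the pole:
mRNA decorates the region around the PCM instead of collapsing onto its
center, matching how smFISH spots distribute around an organelle and
keeping single-molecule detection in a physically meaningful regime.
Directions are re-drawn (never distances) until a point falls inside the
cell, so the distance law is preserved exactly — which is what the
quadrature oracle tests assume. Remaining spots are uniform over the
cell volume; the uniform-background fraction is a free calibration
parameter (the source data do not constrain it).

**Other structure.** Centrosomes are isotropic Gaussian blobs of
SD = radius/2 (nominal radius 1.0 µm, matching the ~1 µm mitotic PCM) on
the reference channel, 1–2 per cell, 3 µm apart. Exactly
`round(translating_fraction × n_spots)` spots carry a colocalized
N-terminus source (8 × 10³ photons) and never a C-terminus source; the
C-terminus channel is diffuse background only. Noise is Poisson on
photon-scaled signal plus additive Gaussian read noise (SD 2), giving
peak spot SNR ≈ 8 at the default spot flux of 1.2 × 10⁴ photons.

**Spot density.** Defaults use 40 spots per control cell. This was
chosen once so that the typical nearest-neighbor spacing stays above the
axial two-point resolution (~1.2 µm at σz = 0.6 µm); at substantially
higher densities neighboring molecules merge optically and *no*
single-scale detector can separate them — in real data that regime is
exactly why spot intensity is used in lieu of molecule counts.
Consequences for interpretation: passing detection tests show the
detector is correct for resolvable fields, not that crowded centrosomal
clusters in real images are countable spot-by-spot.

**Presets.** Relative to `early_M_control` (proximal fraction 0.65,
translating fraction 0.5, PCM flux 5 × 10⁵):

| preset | proximal | translating | PCM flux | spots |
|---|---|---|---|---|
| early_M_control | 0.65 | 0.5 | 1.0× | 40 |
| early_M_emetine | 0.65 | 0.5 | 1.0× | 40 |
| early_M_puromycin | 0.05 | 0.0 | 0.7× | 40 |
| early_M_harringtonine | 0.05 | 0.0 | 0.7× | 40 |
| late_G2 | 0.65 | 0.5 | 0.5× | 40 |
| G1 | 0.20 | 0.2 | 0.25× | 10 |

These encode: dispersal and loss of nascent chains under ribosome
release (puromycin) or run-off (harringtonine) with a 30% PCM reduction
under acute puromycin; no change under the elongation freezer emetine;
a twofold PCM increase from late G2 to early M at constant mRNA count;
a fourfold mRNA-count rise from G1 to late G2. `generate_population`
adds per-cell multiplicative log-normal jitter (SD 0.15 of the log) to
spot count, spot flux and PCM flux; per-cell seeds derive
deterministically from the master seed.

## Detection

Laplacian-of-Gaussian filtering with axis-wise sigmas (µm sigma divided
by voxel pitch per axis), computed at 0.8× the nominal spot sigma — a
slightly under-matched filter sharpens the response and separates close
pairs at a small SNR cost. Candidates are strict 3D local maxima above
`median + k·MAD` of the in-mask response (k = 5 by default; MAD units
make thresholds transfer across intensity scales). Plateaus collapse to
their lexicographically smallest (z, y, x) voxel. Greedy non-maximum
suppression removes any peak inside a 1.5σ ellipsoid of a stronger peak:
flank ripples of a bright source can clear the threshold and must not be
reported as molecules. Sub-voxel positions come from an
intensity-weighted centroid of the background-subtracted image within
2σ; integrated intensity is the background-subtracted sum over a 3σ
ellipsoid (97% of a Gaussian's flux), with local background the median
outside that ellipsoid in the surrounding box. Spots whose peak voxel is
outside the cell mask are discarded; the refined centroid may legally
sit a sub-voxel distance across the mask surface. A single spot scale
per channel is used; multi-scale detection is not implemented.

PCM segmentation: Gaussian pre-smoothing (σ 0.25 µm), threshold
`max(Otsu within the mask, background median + 5·1.4826·MAD)`, connected
components above 0.05 µm³, at most the top two by summed intensity. Per
component: intensity-weighted center of mass, equivalent spherical
radius of the segmented volume, and the sum of the *original*
(unsmoothed) voxel values inside it — no background subtraction inside
the PCM region by default. An alternative level-set rule (contour at
exp(−2) of peak − background, the 2-SD surface of a Gaussian body) is
available via `SegmentationConfig(threshold_mode="level")`.

Local colocalization signals are measured per spot as the mean of a
0.3 µm probe ball minus the median of a 2–3× annulus; positivity means
signal > 3× the annulus MAD. Balls clipped by the stack edge are
computed over available voxels and flagged.

## Radial statistics and comparisons

Each spot is assigned to the nearest centrosome center of mass
(Euclidean, µm; ties to the brightest body). Per cell, spot intensities
are summed in half-open [a, a + 0.5) µm bins with a terminal overflow
bin (default max distance 15 µm) and normalized by the cell's total spot
intensity, so cells with different expression contribute equally;
fractions sum to 1 within 1e-9 by construction and by test. Spots inside
the PCM body stay in their natural bins. Cross-cell aggregation is the
unweighted per-bin mean with a Student-t 95% CI (n − 1 df); a seeded
percentile bootstrap (10⁴ resamples) is available behind a flag.
Replicate-level nesting is not modeled.

The dispersal summary statistic is the intensity-weighted fraction of
mRNA within 3 µm (configurable) of the nearest centrosome. Translation
calling uses the epitope table — translating ⇔ N⁺ ∧ C⁻, ambiguous ⇔
N⁺ ∧ C⁺ (full-length protein coincident with mRNA, kept in denominators
by default), mRNA-only otherwise — restricted to shell members
(1 ≤ d < 3 µm, half-open). The shell translation fraction is
intensity-weighted by default (count weighting by flag), consistent with
intensity standing in for mRNA amount; cells with no shell spots are
excluded and logged.

Condition comparisons use Welch's two-sided unpaired t-test by default;
a `classic` flag restores the pooled-variance Student's t for parity with
the original analysis. Reported: group means, fold change, percent
change, t, p, and a 95% CI of the mean difference. Zero-variance
degenerate inputs are flagged with t = 0, p = 1. The kinetics
calculators are exact arithmetic: capacity = ⌊transcript/spacing⌋
(floor = physical occupancy; the literature's "40" is a rounded upper
bound) and synthesis time = CDS length / elongation rate.

## Numerical and design notes

- Axis order (z, y, x) everywhere; physical units µm; voxel i spans
  [i·d, (i+1)·d) with center (i+0.5)·d.
- Determinism: a fixed seed reproduces images, ground truth and all CSV
  outputs bit-for-bit; all stochastic tests are seeded.
- Problem sizes in the validation suite: 30 cells/condition and 10
  master seeds for effect-size recovery (the scale at which the jitter
  SD of 0.15 makes population means stable to a few percent); 10–20
  single cells for detection quality and null calibration; 1,000 random
  instances for the brute-force binning oracle.
- The mRNA count is the detected spot count; at the default density
  optical merging loses ~8% of molecules, which cancels in the
  between-condition count *ratios* the analysis reports. An
  intensity-deconvolved count (total/median intensity) is available.
- Known limitations: no deconvolution, no multi-scale spots, no
  hierarchical replicate model, no microtubule/motor dynamics, no
  time-lapse; stage labels are inputs, never inferred from images.
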