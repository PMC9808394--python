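# Methods

## Scope and model of the data

`sgscreen` analyses 2D three-channel fluorescence fields from a stress-
granule (SG) reporter line: a nuclear stain (Hoechst), a Venus-tagged FUS
reporter that is nuclear-enriched at rest and forms cytoplasmic puncta when
recruited into SGs, and an mCherry-tagged G3BP1 reporter whose puncta mark
SGs themselves. The screening readout is per-cell and compartment-resolved:
how much granular reporter signal sits in the cytoplasm versus the nucleus,
and what fraction of cells carry cytosolic granules at all.

Because the original screen's raw images are not deposited, the package
ships a generator that emulates the acquisition class (40× objective,
16-bit, 1024×1024 px at ≈0.65 µm/px, 384-well plates seeded at 3,000
cells/well) with full ground truth, at two tiers:

* **image tier** — rendered fields for testing segmentation and
  measurement;
* **tabular tier** — per-well true readouts simulated directly, for
  testing the screening cascade at library scale (a multi-thousand-well
  image screen is not desk-scale, and the cascade's contracts are about
  readouts, not pixels).

## Synthetic fields

Cells are ellipses (cytoplasm) containing a smaller, jittered nuclear
ellipse. Centres are rejection-sampled with a minimum spacing of 36 px —
deliberately less than two cell diameters so neighbouring cells touch and
exercise clump breaking, while nuclei stay disjoint. Compartment base
intensities derive from a per-channel expression level split by a
cytoplasmic fraction (FUS: 5 % cytoplasmic in the control condition, 30 %
under full stimulation; G3BP1: 60 % cytoplasmic throughout). Granules are
isotropic Gaussians with radius defined as 2σ (default radius 2.5 px, peak
amplitude 150 ≈ 10× the noise sd) whose closed-form integrated intensity
`peak · 2πσ²` is recorded in the ground truth. Noise is additive Gaussian
(sd 15), clipped at ±4.5 sd so a background pixel never exceeds
background + 5 sd; there is no Poisson shot noise, PSF, vignetting or
focus drift — passing tests therefore demonstrate contract correctness on
clean, well-behaved images, not robustness to real-microscope artefacts.

Three named conditions parameterize the biology: `control` (no SGs),
`CLM` (DNA damage: G3BP1 SGs form in 80 % of cells, the P525L FUS reporter
joins them in 25 %), and `CLM+NU7441` (DNA damage + DNA-PK inhibition: FUS
joins SGs in 70 % of cells). These probabilities are calibration choices —
the source experiments report images and relative readouts, not per-cell
rates. A cell flagged SG-positive receives a zero-truncated Poisson number
of granules (mean 4); FUS granules are planted at the positions of the
cell's G3BP1 granules with probability 0.9, reflecting co-recruitment into
existing SGs. Granule centres keep 3 granule-radii from every other
granule of the same channel and a wider berth (4σ + 2 px) from the bright
nuclear compartment; granules that cannot be placed under these
constraints are dropped and the ground truth records only what was
rendered. SG flags are cleared for the rare cell whose granules could not
be placed at all, so flags always have image support.

Compound effects follow a Hill law, `f(d) = d^h / (d^h + IC50^h)`, applied
to the stimulated baseline: the FUS- and G3BP1-granule probabilities are
scaled by `1 − f` and the cell count binomially thinned by the toxic
effect. The library generator plants four well-separated classes (the
classes a dual-readout cascade must distinguish): true hits
(FUS IC50 log-uniform in [0.1, 0.75] µM ⇒ ≥ 80 % inhibition at 3 µM),
SG disruptors (the same potency on both FUS and G3BP1, since dissolving
the G3BP1 scaffold removes FUS puncta too), toxic compounds (≥ 60 % kill
at 3 µM) and inactives.

## Segmentation

All steps are deterministic; parameters live in `SegParams` with these
defaults, calibrated once against the generator's default conditions:

| parameter | default | meaning |
|---|---|---|
| `nucleus_min_area` / `nucleus_max_area` | 60 / 2500 px² | nucleus sieve band |
| `seed_erosion_radius` | 8 px | iterations of guarded erosion for seeding |
| `cell_sensitivity` | 2.0 | cell threshold, in noise-sd above background |
| `granule_threshold` | 5.0 | granule peak height, in smoothed-noise sd |
| `granule_min_area` / `granule_max_area` | 4 / 400 px² | granule sieve band |
| `granule_selem_radius` | 3 px | structuring element of the top-hat |
| `border_margin` | 2 px | border-object removal band |
| `smooth_sigma` | 1.0 px | Gaussian pre-smoothing |

**Nuclear seeds.** The nuclear channel is smoothed, thresholded by Otsu
(guarded against blank fields, where Otsu would split pure noise), sieved
at `nucleus_min_area`, then eroded iteratively with a unit disk. The
erosion is *guarded*: an object whose next erosion would remove it
entirely keeps its current pixels. Thin necks between touching nuclei
still break — which is the point of seeding — but an isolated nucleus can
never be lost, so the seed count is robust across nucleus sizes.
Connectivity is 8-connected throughout (diagonal one-pixel slivers remain
single objects).

**Nuclei.** Seeded watershed on the distance transform of the nuclear
foreground splits clumps along the neck between seeds; objects outside the
area band or touching the border margin are removed. Each nucleus carries
its seed's label. Seeds outside the foreground are dropped with a logged
warning.

**Cells.** The reporter channel is thresholded at
`background + cell_sensitivity · sd` — low, to keep weak cytoplasmic
signal — with background and noise estimated robustly (median and MAD;
valid while background occupies the pixel majority, which holds at
screening densities). After hole filling, cells flood outward from the
nuclei on the distance-to-nearest-nucleus transform, so the boundary
between touching cells is equidistant between their nuclei. Regions
without a nucleus are discarded: the per-cell nuclear/cytosolic
decomposition requires a nucleus, so anucleate fragments cannot be
measured anyway. Cell labels equal nucleus labels.

**Granules.** Background is estimated by top-hat-by-reconstruction:
grayscale reconstruction (by dilation) of the eroded image under the
image. Unlike a plain opening it follows compartment edges exactly, so
the bright nuclear rim produces no ring artefacts; unlike an h-dome it
removes only structures smaller than the structuring element, so the
nuclear plateau itself is never mistaken for a granule (the element,
radius 3, is far smaller than any nucleus). Candidate pixels must rise
`granule_threshold` smoothed-noise sd above this background; a hysteresis
threshold extends each accepted peak down to half that height so that
granules partially shadowed by the reconstruction (e.g. near the nuclear
rim) keep their full support and centroid. Components are sieved by area;
an intensity sieve is available through the same threshold parameter.

**Linking.** Each granule joins the cell holding the strict plurality of
its pixels (ties to the lower label; plurality-background granules stay
unassigned), and is nuclear iff the strict majority of its pixels lie in
the owning cell's nucleus. This majority rule is deterministic and
directly checkable against a per-pixel counting oracle.

## Quantification

A granule's integrated intensity is the sum of the background-subtracted
image over its mask — the "density × area" reading of granule signal
(mean intensity × area = integrated intensity). Per cell and channel:
total = Σ over linked granules, nuclear = Σ over in-nucleus granules, and
cytosolic is *computed as* total − nuclear, so the decomposition holds
exactly, not merely to tolerance. A cell is SG-positive when its
cytosolic granule count ≥ 1 and its cytosolic intensity clears a floor
(default 0); the floor exists to reject single-pixel noise on real data.
Well summaries are means and fractions over cells; zero-cell wells are
flagged rather than silently averaged. Percent-of-control normalization
divides by the mean over same-plate stimulus-plus-vehicle control wells,
so the control mean maps to 100 by construction.

## Screening cascade

Thresholds (all percent of control, all configurable in
`CascadeParams`): viability ≥ 70, FUS readout ≤ 40, G3BP1 readout ≥ 50,
primary dose 3 µM, confirmation doses 10/3/0.3/0.03 µM. The FUS/G3BP1
readout is the per-cell cytosolic granule count by default, with summed
cytosolic intensity as a config switch (`readout: intensity`) — screens of
this design have used both, and the cascade logic is identical. All three
primary flags are always computed (a failed upstream filter does not mask
downstream readouts), but the hit call requires all three.

Confirmation fits a bounded 4-parameter logistic to percent inhibition in
log-dose (bottom ∈ [0, 100], top ∈ [0, 120], IC50 within
[min dose/10, max dose×10], hill ∈ [0.2, 5]; five IC50 starts, best
least-squares solution kept; flat series are flagged non-converged rather
than fitted). *Concentration dependence* — usually stated only
qualitatively in screening protocols — is made explicit here as: a
convergent fit, a fitted span above a noise
floor (4× the control wells' apparent-inhibition sd, with
`min_fit_quality` = 20 percentage points as a lower bound), and responses
non-decreasing in dose within `monotonicity_alpha` = 10 points. This
rejects flat series and single-dose spikes. A compound is confirmed iff
it is dose dependent and viability and G3BP1 preservation hold at every
dose where the FUS filter passes (at least one). Compounds with missing
dose rows are flagged unevaluable and excluded with a warning.

Chemical-neighbour expansion of primary hits (testing structural
analogues in the confirmation round) is an externally supplied candidate
list, not computed: compound-similarity search is chemistry outside this
package's scope.

## Numerical and design notes

* Pixel coordinates are 0-based (row, col); labels are consecutive
  positive integers with 0 = background.
* Determinism: every stochastic step flows from one seed through
  `numpy.random.SeedSequence` spawning; identical configs reproduce
  byte-identical CSVs. Segmentation contains no randomness.
* Noise floors and thresholds expressed in noise-sd units use the robust
  MAD estimator; the smoothed-noise sd is derived analytically
  (`sd / (2√π σ)` for Gaussian smoothing).
* Test and acceptance runs use 512×512 fields with 50 cells (and 256×256
  for oracle comparisons) rather than the 1024×1024 default — the smaller
  fields preserve every geometric relationship (cell, nucleus and granule
  scales are unchanged) at a quarter of the area, which keeps the suite
  quick; the full-size geometry remains the config default.
* The tabular tier simulates per-well readouts with binomial/Poisson cell
  and granule statistics and a 15 % CV on granule intensity; it shares
  the Hill-effect machinery with the image tier, so cascade tests exercise
  exactly the effect model the image tier renders.

## Known limitations

* No PSF/optics model, no 3D, no time-lapse, no shot noise: segmentation
  performance on the generator is an upper bound, not an estimate of
  field performance on real images.
* The generator's condition probabilities and granule photometry are
  calibration choices, not measured values; quantities that depend on them
  (e.g. absolute SG-positive fractions) are only meaningful relative to
  their planted ground truth.
* The SG-positivity criterion (≥ 1 cytosolic granule above a floor) is a
  documented substitute for an unpublished vendor-software rule.
* `segment_cells` assumes every cell expresses the reporter above the
  low threshold; reporter-negative cells would be discarded together with
  their nuclei.
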