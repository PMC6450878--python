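# Methods

## The recruitment ratio

Each analysed cell contributes one ratio

R = max(POI | ROI2) / mean(POI | ROI1),

where ROI1 is the whole-cell outline and ROI2 the union of all clustered-
receptor attachment sites on that cell. The maximum is taken on raw,
unsmoothed pixels; no background subtraction is applied (a pre-subtraction
hook exists but is off by default); ROI2 pixels lying inside ROI1 are
included in the ROI1 mean. R is invariant under multiplicative intensity
scaling; an additive offset b attenuates it monotonically toward 1, since a
field with ideal enrichment E yields R = (E·c + b)/(c + b) for baseline c.
Positivity is R ≥ threshold with threshold = 2. The inclusive boundary was
chosen because the per-condition percentages this package reports are
defined via "R ≥ 2" conventions; both the threshold and strictness are
configuration options, and the choice only matters for the measure-zero
event R = exactly 2.

## Synthetic field model

The simulator renders one adherent cell per field in three channels
(particle stain, receptor, POI) so every downstream stage can be tested
against known ground truth:

- **Geometry.** A disk cell (default radius 80 px in a 256×256 field) with
  an attachment site on its perimeter: either a "microcolony" (6
  diffraction-limited spots of radius 4 px, jittered around the anchor
  point) or a single "bead" disk of radius 4 px. The 256×256 default is a
  scaled-down stand-in for a 1024×1024, 8-bit acquisition; sizes scale
  accordingly.
- **POI channel.** Recruitment is modelled as mass-conserving relocation of
  a finite cytosolic pool: attachment-site pixels are raised to E·c and the
  remaining cell interior is depleted pro rata, so the whole-cell mean is
  exactly c (+ background b). Consequently, with ground-truth masks and no
  blur/noise, R = (E·c + b)/(c + b) exactly — and R = E when b = 0 — which
  is what the parameter-recovery tests assert to machine precision. A
  purely additive enrichment model would not have this property (the
  enriched pixels would inflate the ROI1 mean).
- **Receptor / particle channels.** The receptor channel carries the
  cluster at `receptor_gain`·c with a dim whole-cell membrane signal
  (8% of the cluster level); the particle channel is non-zero only on the
  cluster footprint.
- **Noise pipeline.** Gaussian PSF blur (σ = 2 px) is applied to the ideal
  image first (photon-limited imaging), then Poisson shot noise, then
  additive Gaussian read noise (σ = 2 counts, clipped at zero), then
  optional quantization to the acquisition bit depth (default 8 bit,
  off by default so analytic test cases stay exact). With a fixed seed the
  output is bit-identical across runs; cohort seeds derive deterministically
  from one master seed, and cells cycle over three pseudo-experiment labels
  ("exp1–3", 20 of 60 each) to exercise the pooled-aggregation path. No
  batch effect is simulated by default; a per-experiment multiplicative
  intensity factor is available.
- **Defaults.** Baseline c = 40 counts/px, background b = 0, E = 3 for a
  recruiting condition and E = 1 for a non-recruiting one. These were
  chosen once, for a realistic mid-range SNR on an 8-bit scale; no
  acquisition SNR is documented for the assay itself. Under these defaults
  the blurred peak is attenuated (the recoverable cohort-mean R at E = 3 is
  ≈ 3.5 after the max-statistic noise bias, ≈ 1.6 at E = 1), which is why
  noisy-recovery tests compare against a ground-truth-mask oracle computed
  on the same fields rather than against E itself.

What the simulator deliberately does not reproduce: Airy/defocus structure
beyond a Gaussian PSF, chromatic offsets, 3D sectioning, multiple or
confluent cells per field, autofluorescence gradients, and receptor
internalisation dynamics. Passing tests therefore demonstrate correctness
of the measurement pipeline on images whose formation model is known — not
segmentation robustness on real micrographs, where hand-drawn ROIs remain
the reference.

## ROI segmentation

ROI1: Gaussian smoothing (σ = 2 px) → Otsu threshold → hole filling →
largest connected component, rejected below 500 px. Otsu on the smoothed
histogram makes the mask invariant under multiplicative intensity scaling.
ROI2: receptor pixels above the 0.995 intensity quantile (cluster pixels
are a tiny area fraction, where Otsu is unstable) → dilation by 3 px (the
micron scale of a particle) → components must touch the 3-px-dilated cell
mask → union of survivors. One ROI2 per cell (one R per cell);
per-component scoring and an optional intersection with the particle
channel exist behind flags. Hand-drawn masks can be imported as 0/255 TIFFs.

## Statistics

Per-condition summaries: mean R, Student-t 95% CI (n − 1 df; the CI method
is not documented for the original assay, t-based is the conventional
reading of mean ± 95% CI whiskers), percent positive = 100 × mean of the
positivity indicator. Testing: one-way ANOVA from explicit sums of squares,
then pairwise two-sided t-tests of each condition against the reference
using the pooled within-group mean square (df = N − k), Bonferroni-adjusted
by the number of comparisons performed (versus-reference by default, all
pairs optionally, mirroring versus-control figure conventions). Stars on
adjusted p: * 0.05, ** 0.01, *** 0.001. The omnibus F/p is cross-checked
against `scipy.stats.f_oneway` in the tests; for two groups F = t² of the
pooled t-test. Degenerate inputs: groups of n < 2 raise; if every group is
internally constant the F statistic degenerates (inf or NaN) and is
reported as such rather than masked.

Monte-Carlo designs (sizes chosen once as the package's validation
conditions): discrimination is checked on 20 master seeds of full
E = 3 vs E = 1 cohorts (n = 60 each, automated ROIs, 256-px fields);
the type-I error of the versus-reference test is estimated by generating a
pool of 1500 ratios from one condition through the full image pipeline
(128-px fields for throughput) and drawing two disjoint n = 60 groups from
that pool per replicate, 1000 replicates — under the null the two groups
are exchangeable draws from the same simulated condition, so the nominal
level applies.

## Motif scanning

Patterns: membrane-proximal talin site N-P-x-[Y/F]; membrane-distal
kindlin-associated site N-x-x-[Y/F]. Coordinates are in precursor
numbering (1-based, including the signal peptide), under which the human
β1 NPIY tyrosine is residue 783; each tail carries the precursor index of
its first residue (β1 spans E762–K798).

Classification is positional: the proximal motif is the first N-P-x-[Y/F]
occurrence starting within the membrane-proximal 60% of the tail; later,
non-overlapping N-x-x-[Y/F] occurrences are distal — including
NPxY-shaped ones such as β1's distal NPKY, which the field assigns to the
distal (kindlin) site. A distal motif is never promoted to proximal: after
a Y783A-type mutation the proximal class is simply absent. When no
proximal motif exists, N-x-x-[Y/F] occurrences in the C-terminal half are
still reported as distal. The 60% bound is a heuristic chosen from the
documented tails (proximal motifs begin near or before the midpoint,
distal motifs near the C-terminus); it is a module constant.

Point mutations use specs like "Y783A" and verify the stated reference
residue against the sequence before substituting, so numbering-offset
mistakes fail loudly.

### Packaged tail panel

`human_itgb_tails.fasta` carries the human β1/β2/β3 tails reconstructed
from the published construct boundaries and the canonical tail sequences
(β2 termini additionally consistent with the published cloning primers).
`extended_itgb_tails.synthetic.fasta` carries **synthetic stand-ins** for
human β5–β8 and the two *Capsaspora owczarzaki* tails: plausible tail-like
sequences engineered to carry exactly the documented motif content (β5/β6/
β7 with a proximal NPxY, β8 with none, both *Capsaspora* tails with a
proximal NPxY/NPxF-class motif) — not the authentic residues, which were
unavailable when the panel was assembled. Conclusions drawn from the panel
are therefore about the scanner's behaviour on the documented motif
pattern, not new claims about those sequences. β4 is omitted from the
panel (its cytoplasmic domain is three orders of magnitude longer than the
others and is conventionally excluded from tail alignments); the scanner
itself handles arbitrary-length tails.

## Numerical and design notes

- Blur before noise; quantization last and optional. Intensities are
  clipped at zero after read noise so channel non-negativity holds.
- The enrichment relocation model requires E·(cluster∩cell area) <
  cell area; violating geometries raise an invalid-geometry error, as do
  clusters that miss the cell entirely.
- Line scans use bilinear interpolation and per-channel normalisation to
  the maximum along the segment; identically zero channels are reported as
  zero rather than divided.
- Cohort processing never aborts on a per-cell failure: no-cell,
  no-cluster and undefined-ratio conditions become logged exclusions.
- End-to-end runs are deterministic given the master seed; the run
  manifest records versions, seed, parameters and exclusions.

## Known limitations

- Automated ROIs are validated only against synthetic ground truth; the
  original measurements used hand-drawn ROIs, for which no reproducible
  rule exists.
- The max-in-ROI2 statistic inherits a positive noise bias that grows
  (slowly) with ROI2 area, so R under noise is not an unbiased estimate of
  E; comparisons between conditions measured with the same settings are
  unaffected.
- Percent-positive is reported without a CI; at n = 60 its binomial SE is
  about 6 percentage points at 50%.
- The pooled-error Bonferroni post-hoc assumes homoscedastic groups, as
  does the original analysis convention it mirrors.
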