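# Methods

## The PCC enrichment statistic

The package's central measurement treats a chromocenter as a 1-D problem: a
fluorescence intensity profile is sampled across the chromocenter midline
and all downstream quantities are computed on that trace.

**Profile extraction.** The line runs through a user-supplied center (for
synthetic data, the planted centroid) in a configurable in-plane direction
(default: the image x-axis, since real midline orientations are an
acquisition choice, not a property of the data). Samples are placed at half
the smaller in-plane pixel pitch and interpolated bilinearly — fine enough
that delineation is not limited by the sampling grid, without pretending to
resolution the image does not have. For 3-D stacks the profile is taken on
a single z-plane, matching how such panels are measured in practice; no
smoothing or background subtraction is applied before correlation, so the
statistic reflects the raw acquired signal.

**Chromocenter delineation.** The threshold is the arithmetic mean of the
DAPI values of the extracted profile (the plot itself, not the nucleus or
the image — the profile is the object being analysed). The chromocenter is
the maximal contiguous run of samples strictly above that threshold that
contains the global DAPI maximum; a bell-shaped focus on a baseline always
produces such a run, while a flat profile produces none, which is reported
as "no chromocenter" rather than an error. Secondary above-mean runs (e.g.
a neighbouring focus clipped by the profile ends) are counted and ignored;
one profile scores one chromocenter.

**PCC.** The sample Pearson correlation between the DAPI and marker values
restricted to the delineated segment. It is invariant under positive affine
transforms of either channel, so gain and offset differences between
channels do not matter. Segments shorter than 3 samples are rejected; zero
variance in either channel yields an explicitly *undefined* record that
summaries exclude and count, never a silent 0.

## Synthetic study data

The generators produce data with the statistical structure the analyses
assume, plus exact planted truth; they emulate the measurement geometry,
not the optics (no PSF, no photobleaching, no autofluorescence texture —
claims about real images rest on the method, not on these fixtures).

**Nucleus images.** Default: a single 2-D 16-bit section, 0.1 µm pixels, a
5 µm-radius nucleus with nucleoplasm level 2000 counts, containing 4
non-overlapping chromocenters of radius 0.7–1.2 µm placed by rejection
sampling. Each DAPI focus is an isotropic Gaussian with σ = radius/2 whose
peak reaches 3× the nucleoplasm (the visual contrast of DAPI-dense foci);
3-D stacks use a 0.5 µm z-step. Detector noise is additive Gaussian with
σ = 200 counts (≈5% of the focus amplitude, a typical confocal
signal-to-noise regime), with an optional Poisson component for shot-noise
studies.

The marker channel has three modes reflecting the three enrichment
phenotypes the PCC distinguishes:

* `colocalized` — an exact positive affine transform of DAPI inside the
  nucleus, so the noiseless PCC is exactly 1 (the fully-enriched, 16-cell
  like pattern);
* `cloudy` — per focus, a Gaussian shell (σ = ring_width/2, default
  0.4 µm) centred at 0.4× the focus radius. The shell position is the one
  genuinely open geometric choice: a shell at the focus *edge* makes the
  marker rise monotonically across the whole above-mean DAPI segment and
  drives the PCC to ≈ −0.9, below the diffuse mode — the wrong phenotype.
  Placed at 0.4× the radius, the cloud is concentrated in and around the
  DAPI-dense core, the midline profile is bimodal with a shallow dip at
  the DAPI peak, and the PCC lands in the weakly-positive range
  (median ≈ 0.3–0.45) characteristic of a halo that overlaps but does not
  track the chromocenter;
* `diffuse` — spatially uniform over the nucleus, PCC ≈ 0 under noise.

With these defaults the median PCC ordering colocalized > cloudy > diffuse
is stable seed-to-seed with gaps far above 0.1.

**FISH images.** Nuclei are disks on a tile grid; each carries its planted
number of Gaussian spots (amplitude 6000 counts, σ = 0.3 µm) kept ≥ 4σ
apart so "number of foci" is well defined. A spec whose amplitude is below
5× the noise SD is flagged with a warning (the documented detectability
bound) but still rendered.

**FASTQ.** Reads are 50 bp by default; each is satellite-bearing with the
planted probability, embedding one of the eight motifs verbatim at a
uniform offset; background reads are rejection-sampled to be motif-free so
the planted count is exact truth. In bisulfite mode every C is kept with
probability `methylation_rate` and otherwise converted to T with
probability `conversion_efficiency` (default 0.99, typical of real kits),
so the expected assay readout is (1 − methylation) × efficiency. Quality
strings are constant Phred 40; the assays ignore qualities. All generators
are byte-deterministic under (spec, seed), with named substreams split from
one root seed.

## Intensity quantification

Background per channel is the median over a 3-pixel dilation annulus just
outside the nucleus mask — local, robust to bright neighbours (which can be
excluded explicitly), and independent of signal inside the mask. Residuals
below background are clamped to zero before summation so totals are of
non-negative signal, with the clamping flagged. Marker totals are divided
by the nucleus's DAPI total; percent change between groups is computed on
group means of these normalised levels, matching the convention of quoting
a single percent-reduction figure. The inactive-X-style region is the
largest connected component of defining-channel voxels above mean + k·SD
within the nucleus (k = 2 by default; the delineation rule is a package
choice, made explicit and configurable).

The Mann–Whitney U test is two-sided; the exact null distribution is used
when n_a·n_b ≤ 64 with no ties (verified against exhaustive permutation
enumeration), otherwise the tie-corrected normal approximation, and the
method used is recorded in the result. Two groups with all values identical
carry no ordering information and return p = 1 with a degenerate-data flag.

## Focus detection

The FISH channel is band-pass filtered with a difference of Gaussians at
(σ, 3σ) matched to the expected spot size (0.3 µm default). Candidate foci
are local maxima inside the nucleus mask whose filtered response exceeds
the in-mask median by k = 6 MAD-based standard deviations, with maxima
closer than 0.6 µm merged. The threshold is deliberately conservative: a
noise-only nucleus has of order 10³ independent filtered samples, so a 6-σ
robust cutoff keeps false positives rare while spots at the default
amplitude (30× noise SD, ≈0.3–0.5 retained after band-pass) remain far
above it. In 3-D the filter and maxima are computed directly in the
anisotropic volume with per-axis sigmas. Counts map onto the categories
0, 1–2, 3–4, 5+; the map is total and order-preserving, and per-group
fractions always sum to 1.

## Satellite assays

ChIP-style counting is an exact, case-insensitive substring scan of each
read against the eight motifs, binary per read — no mismatch allowance,
because the assay's point is literal tag matching free of mapping bias.
The motif set is validated at load to be exactly eight uppercase DNA
strings closed under reverse complement, which makes the count invariant
under reverse-complementing every read.

Bisulfite conversion is estimated by matching reads against motif variants
in which every C may read C or T (all other positions exact), applied to
the read as given; wildcarding G positions for reads sequenced from the
complementary strand of the converted molecule is deliberately *not*
applied — the C-wildcard convention is documented rather than asserted as
the only possible one, and the RC-closed motif set already covers both
genomic strands. Each matched occurrence contributes one assayed site per
motif C (found via overlapping regex lookahead), tallied converted on T.
Both assays stream the FASTQ in constant memory and abort on a malformed
record with its record number.

## Problem sizes and numerical choices

Validation runs use 100 synthetic nuclei per marker mode (≈400
chromocenters each), 200 FISH nuclei, and 10,000-read FASTQ files — large
enough that binomial/sampling error is small against the tested margins,
small enough to run comfortably on a laptop core. PCC values are clipped to
[−1, 1] against floating-point overshoot; image intensities are kept as
float64 in memory and quantised to integers only when writing TIFF, so
noiseless fixtures preserve exact channel relations (the noiseless
colocalized PCC is 1.0 to 1e-9 in memory; after a TIFF round-trip,
quantisation moves it to ≳0.999).

## Known limitations

* Chromocenter discovery is profile-based, as in the source protocol;
  there is no automatic 3-D segmentation of all chromocenters in a
  nucleus, and only Pearson correlation is offered (no Manders/Costes).
* The synthetic images are geometric phantoms: no PSF, no chromatic shift,
  no intensity gradients. Passing recovery tests demonstrates the
  correctness of the measurement chain, not robustness to every real-world
  artefact.
* Nucleus masks are inputs (from the generators' truth or external
  segmentation tools); the package does not segment nuclei from raw DAPI.
* The real distributions of chromocenter number and size per developmental
  stage are not modelled; generator defaults are configurable conventions,
  not biological claims.
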