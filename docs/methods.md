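# Methods

This note records what `archaeotype` computes, the assumptions behind each
stage, the defaults and why they were chosen, and what the synthetic-data
experiments do and do not demonstrate.

## Signal model and preprocessing

A raw spectrum is a profile trace of intensity versus m/z over the
acquisition window (default 2,000–20,000 Da, linear positive mode, singly
charged ions assumed, so m/z approximates molecular mass). The processing
chain is:

1. **Savitzky–Golay smoothing** — width 5 m/z, 1 cycle, polynomial
   order 2. The width is interpreted as the *full* window span and
   converted to the nearest odd point count from the local sampling step;
   a grid whose step drifts more than 20% is rejected. Order 2 is the
   standard choice for linear-mode MALDI profiles (the filter reproduces
   constants and quadratics exactly); endpoints are handled by fitting the
   polynomial on the truncated window.
2. **Top-hat baseline correction** — the baseline is the grayscale opening
   (erosion, then dilation) of the signal with a flat structuring element,
   default span 150 Da: much wider than a peak (~5 Da) and much narrower
   than the baseline's variation scale over the 18 kDa window. The signal
   is padded by linear extrapolation of its edges before the opening and
   cropped afterwards; with edge-value or reflective padding a flat
   element systematically under-removes a sloping baseline inside the
   first and last half-window. Opening is anti-extensive, so the corrected
   signal is ≥ 0 pointwise.
3. **Noise estimation** — the robust scale of the signal-free background:
   median absolute deviation of the first difference, × 1.4826 / √2 (the
   Gaussian-consistent estimate of the pointwise sigma). Differencing
   removes slow structure and the MAD ignores sparse peaks. In the full
   chain the noise is estimated on the baseline-corrected but *unsmoothed*
   signal: smoothing both shrinks and correlates the background, which
   biases the difference-MAD low and would let near-threshold noise maxima
   through the S/N gate.
4. **Centroid peak detection** — local maxima with height/noise ≥ 3 are
   kept (at most 100 peaks; maxima closer than the 5 m/z peak width are
   merged keeping the taller; trimming to the cap is a stable sort by
   intensity descending, then m/z ascending). Heights are measured above
   the *median* of the corrected signal: the opening of a noisy trace sits
   at the noise's lower envelope, leaving a positive pedestal of roughly
   2.5 σ that would otherwise inflate every height and admit hundreds of
   background maxima. Each kept maximum is centroided as the
   intensity-weighted mean m/z of its contiguous above-half-height region,
   which must span at least half the peak width (this rejects
   single-sample spikes). Intensity is reported as height, not area,
   matching fingerprint practice. When the noise estimate is exactly zero
   (idealized noiseless input) a relative height floor of 10⁻³ of the
   tallest peak stands in for the S/N gate.

The chain is deterministic: identical input and configuration give a
bit-identical peak list.

## Peak matching

Two peaks match when their m/z difference is at most
max(2 Da, 600 ppm · m/z) — roughly 2–12 Da across the window, consistent
with linear-mode mass accuracy. Pairing is one-to-one and greedy by
ascending distance. The same tolerance is shared by MSP construction,
scoring, and clustering, and is configurable everywhere. The generator's
default mass jitter (300 ppm) sits well inside this tolerance by design;
stress configurations can exceed it.

## Reference spectra (MSPs)

A strain's reference spectrum is built from replicate peak lists (10–24
recommended; fewer warns but proceeds):

- **Replicate QC** — for each replicate, the *proportion of reproducible
  peaks* is the fraction of its peaks matching the provisional consensus —
  the peak positions present in at least 50% of the *other* replicates.
  Replicates whose proportion is not strictly higher than 0.6 are
  rejected; every rejection is logged with the rule that fired. Whether
  the original instrument software computes this against a consensus or
  pairwise is not publicly documented; the consensus definition used here
  is explicit and configurable.
- **Consensus peaks** — surviving replicates' peaks are pooled, sorted,
  and single-linkage clustered (split where the gap between consecutive
  peaks exceeds the tolerance). Each cluster yields mean m/z, mean
  intensity, and frequency = (replicates containing a member) / (accepted
  replicates). Medians are available via configuration. Clusters in fewer
  than 25% of accepted replicates are dropped, and the reference is capped
  at 70 peaks by (frequency, then intensity, descending); cap and minimum
  frequency follow common fingerprinting practice.

The build is permutation-invariant in replicate order.

## Identification score

v₁ (reference peaks matched / reference peaks), v₂ (candidate peaks
matched / candidate peaks), and v₃ — the intensity symmetry of the matched
pairs, implemented as the rank correlation between matched candidate and
reference intensities, clamped to [0, 1]. Fewer than 3 matched pairs gives
v₃ = 0 (the correlation is unstable and this is logged); intensities
constant on both sides count as perfect symmetry, constant on one side
only as none. The score is log₁₀(1000 · v₁v₂v₃), floored at 0 when the
product is ≤ 10⁻³ so that scores stay in [0, 3] as the interpretation
bands presuppose. Bands: ≥ 2.30 highly probable species; 2.00–2.29 secure
genus / probable species; below 2.00 "not reliable" (the published banding
stops at 2.00; the label for everything below it is ours). The score is
invariant to rescaling candidate intensities, is at most 3, and equals 3
exactly iff v₁ = v₂ = v₃ = 1.

Re-identification scores replicate peak lists (normally 3) against one
reference and reports mean ± sample standard deviation. The "±" term is
labelled explicitly as sample sd.

No numerical equality with proprietary commercial scores on real data is
claimed — fidelity is to the published description of the computation.

## Dendrograms and gel views

The distance level between two references is (1 − s)·1000 with s the
geometric mean of the two directed three-value products (each reference
scored with the other as candidate). This is a committed reading of a
distance "calculated from the three values"; the exact commercial formula
is unpublished. The distance is a bounded symmetric premetric (no triangle
inequality claimed). Libraries are sorted by strain id before
average-linkage agglomeration (single/complete available), making the
dendrogram invariant to input order and fixing tie-breaks. Newick export
uses ultrametric branch lengths (a merge at height *h* is at depth *h*/2),
quoting labels that contain spaces or reserved characters. The gel view
bins reference peaks into m/z bins (default 10 Da) and orders rows by
dendrogram leaves.

## Biomarker masses

Average molecular mass = sum of isotope-averaged residue masses + one
water (18.01524 Da), the convention of standard pI/Mw calculators; the
monoisotopic table is included for completeness but linear-mode work uses
averages. Mass error is 100·|observed − predicted| / predicted — the
predicted-mass denominator reproduces the published error columns;
an observed-mass variant is available. Display rounding is half-up to two
decimals, with full precision kept internally. The database search returns
every protein within the window (default 1%), sorted by error. Isoelectric
point is deliberately not computed. The truncation scan enumerates
N-terminal prefixes and/or C-terminal suffixes by cumulative residue sums
(O(L)); an all-contiguous-substrings mode exists for mid-chain fragments
at O(L²) cost.

## Synthetic data

The generator emulates what the pipeline needs from real acquisitions, not
archaeal biology:

- a strain is 5–100 Gaussian peaks (σ = 2.5 Da) with minimum spacing 4σ,
  base intensities log-uniform over two decades (100–10,000 a.u.);
- a replicate applies per-peak dropout (p = 0.1), 300 ppm Gaussian mass
  jitter, log-normal intensity variability (CV 0.25), Poisson spurious
  peaks (rate 2, one decade of intensity), an exponential baseline
  (amplitude 300, scale 3,000 Da), a constant detector offset of 6 ×
  noise_sd (keeping the trace non-negative, as detector counts are,
  without clamping the noise distribution), and white noise (sd 20, so
  planted true S/N spans 5–500) on a 1 Da grid;
- panels plant a taxonomy by drawing one globally well-spaced position set
  (25 Da minimum spacing, wider than the matching tolerance anywhere in
  the window, so distinct pools can never cross-match) and assembling each
  strain from background (10%), genus (50%), species (30%), and private
  (10%) pools — giving 0.9 / 0.6 / 0.1 expected sharing within species /
  within genus / across genera. Shared peaks keep a shared base intensity,
  as conserved proteins do. Replicates default to 12 per strain, inside
  the recommended 10–24 range.

Everything is a pure function of (model, config, seed).

What passing tests show: the implementation recovers planted peaks
(recall ≥ 0.95 at true S/N ≥ 5, false discovery ≤ 0.05), identifies
strains against their own references inside the species band, and
recovers planted genus structure in dendrograms — under this statistical
model. What they do not show: performance on real archaeal fingerprints,
whose peak shapes, baseline chemistry, detector saturation, and
mass-dependent resolution the generator does not imitate, nor agreement
with any proprietary implementation on real data.

## Problem sizes used in validation

The validation suite uses 30-peak strains, 10-replicate library builds,
ten-strain two-genus panels over 20 seeds, 50-replicate recall
experiments, a 1,000-protein synthetic database for window-search
completeness, and 100 construct-then-recover truncation scans. These sizes
give stable statistics for every asserted property while keeping the whole
suite fast enough to run routinely.

## Known limitations

- No recalibration against external calibrants, no isotope deconvolution,
  no charge-state inference (linear mode, singly charged assumed).
- No proprietary instrument file parsing; profile spectra travel as
  two-column text/CSV, an interchange contract this package defines.
- The reproducibility proportion, noise estimator, centroid region, and
  distance formula are documented choices where the published description
  is silent; alternatives are configurable but the defaults are committed.
- Strain and replicate identity come from explicit arguments or metadata
  sidecars, never filename guessing.
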