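# Methods

This note documents the models and procedures implemented in `syrinxlab`,
the parameter choices that matter, what the synthetic generators do and do
not emulate, and the numerical conventions used throughout.

## Twitch and tetanus metrics

A twitch recording is a uniformly sampled force trace (20–40 kHz typical).
The baseline is the mean force over a configurable window (default 10 ms)
preceding the stimulus; the paper-standard t₅₀₋₅₀ contraction-speed metric
is the interval between the first upward and the first subsequent downward
crossing of baseline + ½(peak − baseline). Crossings are located by linear
interpolation between adjacent samples, so the FWHM has sub-sample
precision; against a 1 MHz-oversampled crossing search on the analytic
waveform the sampled estimate agrees to well under 0.1 % at 40 kHz. FWHM is
invariant under amplitude scaling and time shifts by construction. A trace
whose peak does not exceed baseline raises "no contraction"; a missing
crossing on either flank raises "incomplete twitch". Sessions are the
standard in-vitro protocol of seven twitches and three 100 ms tetani;
because it is not obvious whether speed should be reported from a
representative twitch or the session average, `summarize_session` emits
both per-twitch metrics and their arithmetic mean.

Cross-sectional area uses the mass-density route:
CSA = (m_dry · c) / (ρ · L₀) with dry-to-wet factor c = 5 and muscle
density ρ = 1060 kg·m⁻³. Maximal isometric stress divides the global
maximum of the baseline-subtracted tetanic force by CSA; no plateau fit is
attempted (a plateau model would change nothing for monotone-rise traces
and adds a failure mode for noisy ones). Internal arithmetic is SI;
reported units are mN, ms, mm², mN/mm².

## Myofibre segmentation

The chain follows standard practice for laminin-outlined muscle sections:

1. optional rescale to a target height (bilinear for channels,
   nearest-neighbour for masks; the whole-section workflow rescales to
   10,000 px);
2. CLAHE on the laminin channel (clip limit 0.01, default tile grid);
3. hemisyrinx mask applied;
4. global Otsu threshold on the masked, equalized channel, lowered by a
   configurable fraction (default 0.15, sensible range 0.10–0.20) so that
   dimmer basal-lamina segments still register as border;
5. removal of interior components below 50 µm² (vessels, nerves,
   sarcoplasmic reticulum profiles) and filling of holes up to 30 µm²;
6. closing with a diamond structuring element (radius 1) to smooth
   interiors;
7. Euclidean distance transform of the interiors;
8. H-minima suppression (depth 2 px) of the inverted distance map,
   implemented as greyscale reconstruction by erosion — this merges
   shallow minima that would otherwise fragment single fibres;
9. watershed with 8-connectivity, seeded by the surviving regional
   minima, confined to the interior mask.

The chain is fully deterministic. Label 0 is background; labels ≥ 1 are
disjoint and lie inside the mask. An empty mask yields an empty label map;
a flat laminin channel raises "no borders detected".

Feature extraction measures area, perimeter, eccentricity, solidity,
ellipse axes/ratio and circularity = 4πA/P² (capped at 1, since pixelated
perimeters of small discs can push the raw value slightly above the
continuous bound), plus the mean MY-32 intensity per label. False
detections are removed by constraints — defaults area ∈ [50, 2500] µm²,
solidity ≥ 0.80, circularity ≥ 0.30, all configurable and logged when they
fire. The published workflow used such constraints without stating values;
these defaults bracket real syringeal fibre geometry (100–1000 µm²,
compact convex profiles) with generous margins.

Typing is a strict intensity threshold on the 8-bit scale: mean MY-32 > 50
is "fast", ≤ 50 "superfast" (the boundary value belongs to superfast).
Other bit depths should be rescaled to 0–255 before classification. The
hemisyrinx CSA dilates the union of fibre labels with a diamond of radius
10 px to fill the inter-fibre space before measuring area. Histograms of
fibre area and MY-32 intensity use fixed bin widths (50 µm², 5 intensity
units) and probability-density normalization so sections with different
fibre counts are comparable.

## Song acoustics

Recordings are calibrated to pascal via the 1 Pa / 1 kHz reference-tone
chain, bandpass filtered once per recording (200–12,000 Hz, 2nd-order
Butterworth, forward–backward so transients keep their timing), and framed
into 4 ms windows advanced by 0.5 ms. Per frame:

- **power** — mean squared pressure;
- **source level** — 10·log₁₀(power / (20 µPa)²), i.e. dB rms re 20 µPa at
  the 1 m calibration reference; silent frames report −inf;
- **Wiener entropy** — 10·log₁₀ of the geometric/arithmetic mean ratio of
  the 512-point Hann-windowed power spectrum, floored at 1e−12, evaluated
  over bins inside the analysis band only (outside it the bandpass filter,
  not the signal, would set the flatness). White noise sits near −2.5 dB
  (the chi-square bias of periodogram bins), pure tones far below −20 dB;
- **f₀** — the Yin estimator: difference function over an integration
  window, cumulative-mean-normalized difference (CMND), first lag with
  CMND below the absolute threshold 0.15 (descending to its local
  minimum), parabolic interpolation of the minimum. The search range is
  300–8000 Hz by default, and the integration window extends to twice the
  longest candidate period, which the low end of the range requires; the
  difference function is computed exactly with cumulative energies and
  FFT cross-correlation, vectorized over frames. On 6–10-harmonic stacks
  from 500–4000 Hz the estimate is within ~0.5 % of truth;
- **aperiodicity** — the CMND value at the chosen lag, clipped to [0, 1];
  0 means a perfectly periodic frame. This is our operational definition
  of the per-bin aperiodicity feature.

Motif detection cross-correlates the RMS amplitude envelope (frame grid)
with a template envelope, using Pearson correlation per lag so that
non-negative envelopes do not inflate the score; peaks above 0.5 with
non-overlap suppression of one template length become candidates. Each
candidate is then shifted (±10 ms) to maximize correlation of its
source-level trace with the session reference (first detection). If a
source-level threshold is supplied, each motif is segmented and motifs
whose (syllable count, 20 ms-quantized durations) signature differs from
the modal syntax are dropped. Motif source level is the energy-weighted
mean of frame source levels over sound frames.

Syllable segmentation thresholds the frame source level at a fixed
per-bird value, then applies the two duration rules in a fixed order:
sound runs < 30 ms are removed first, then interior silence runs < 40 ms
are removed, merging their flanking sounds (leading/trailing silences are
left alone — they have no sound on both sides to merge). The order
matters in edge cases and is configurable; short-sounds-first was chosen
because isolated blips should not be allowed to bridge long gaps. The
procedure is idempotent, and motif duration equals the sum of emitted
syllable and gap durations exactly (last offset minus first onset on the
0.5 ms grid).

Per-syllable f₀ statistics first clean the trace: split at adjacent-frame
jumps > 100 Hz or missing frames, drop segments shorter than 5 ms, and if
the surviving frames cover less than 50 % of the syllable, mark pitch
non-robust and emit NaN statistics. The 50 % coverage criterion is this
package's quantification of "robust pitch detection" — it is a design
choice, not a published value. Cleaning only ever removes frames.

Pre/post comparison: per syllable and feature (mean f₀, f₀ range, mean
Wiener entropy) an unpaired two-sided t-test labels the change increase /
decrease / ns at α = 0.05; syllables with fewer than 2 motifs in either
condition are excluded with a warning. Per animal, paired two-sided
t-tests compare mean motif duration and source level. Under the null the
significant fraction is calibrated at the nominal 5 %.

## Proteomics

Quantification order: exclusion → pooling → top-3 → normalization. The
five red-blood-cell accessions (A0A674HE74, B5FXM1, B5G3P7, H0ZSY4,
A0A674HG19) are removed by exact set membership — never substring
matching. Peptides flagged as shared across the fast/developmental MyHC
cluster are pooled into a single "MYH-fast" pseudo-protein before top-3
(MYH13, identifiable by unique peptides, stays separate); the flag is an
input column because peptide-to-genome mapping is out of scope here.
Top-3 abundance is the sum of the three largest peptide areas (the plain
sum when fewer than three peptides exist), so adding a smaller fourth
peptide never changes it. Both normalizations are computed after
exclusion: rel_total (fraction of the summed top-3 pool, which sums to 1
by construction and includes Histone H4 in the denominator by default)
and rel_h4 (ratio to Histone H4, accession B5FXC8; exactly 1 for H4
itself). If H4 was not observed, rel_h4 is omitted with a warning.

Differential abundance uses rel_h4 by default: ratio-to-reference
normalization preserves per-protein fold changes, whereas the
compositional rel_total distorts them whenever a dominant protein (the
MyHC pool) moves. The fold change is the geometric mean of per-pair
treated/intact ratios — exactly the injected value on noiseless pairs —
and the test is a paired two-sided t-test on per-pair log₂ ratios. The
phrase "paired Welch" is internally inconsistent (Welch's correction
applies to unpaired comparisons), so paired-on-differences is the primary
test with an unpaired Welch option. Raw p-values are reported;
Benjamini–Hochberg correction is available behind a flag but off by
default. Proteins missing from any sample get NaN fold change and are
excluded from testing. Category rollups sum relative abundance over the
four groups (sarcomeric, Ca-handling, mitochondrial, other).

## Preference analysis

Stimulus matching: a motif is eligible when its duration is within 4 ms
and its source level within 2 dB of its condition's mean (the published
"1–2 dB" range is resolved as a single configurable window, default
2 dB); if either eligible set is empty both windows widen to 30 ms / 6 dB
before erroring out. One motif per condition is drawn uniformly from the
eligible set with a seeded generator. Motif exchange into a bout uses
5 ms cosine cross-fades at the splice points (fade length is a
click-avoidance choice, not a published value).

Preference is the pooled 4-day fraction of pecks for the focal stimulus,
with each peck mapped to its stimulus through the nightly-switched
key assignment; pecks are attributed to test days by their logged day
field. Significance uses the goodness-of-fit G statistic
G = 2·Σ Oᵢ ln(Oᵢ/Eᵢ) against a 50:50 null with Williams' correction in
the standard k-cell form q = 1 + (k²−1)/(6n(k−1)), hence q = 1 + 1/(2n)
for two cells, and G/q referred to χ²(1). The correction always shrinks G
and vanishes as n grows. Days are pooled (no per-day homogeneity test),
matching the published analysis description.

## Synthetic generators

The generators emulate the statistical and geometric structure each stage
consumes; they are not photorealistic histology or naturalistic birdsong.
Passing recovery tests therefore demonstrates that the analysis chain is
correct and well calibrated on data of known structure — not that it is
robust to every artefact of real microscopy or field recordings (uneven
illumination, stain gradients, cage noise, reverberation are out of
scope).

- **Twitches** are two-exponential transients
  A(e^(−t/τ_d) − e^(−t/τ_r)) with τ_d/τ_r = 4 by default; since FWHM
  scales linearly with τ_r at fixed ratio, the rise constant is set from
  a root-found unit FWHM so the true FWHM equals the target exactly
  (default 4.89 ms, the intact adult value). Tetani rise exponentially to
  a plateau over the 100 ms stimulation and relax exponentially. Session
  mode emits 7 twitches + 3 tetani.
- **Sections** place elliptical fibres on a jittered grid (so fibres
  never touch, leaving a realistic interstitium), types drawn Bernoulli
  at the configured superfast fraction (default 0.66), areas uniform in
  200–1000 µm² (superfast) or 100–400 µm² (fast) with rasterized areas
  iteratively rescaled into range. MY-32 intensities are N(20, 8²)
  (superfast, clipped ≥ 0) and N(120, 30²) (fast, clipped ≤ 255): the
  published workflow gives only the > 50 cutoff, so these distributions
  were chosen to straddle it with a realistic ~1 % overlap. The laminin
  channel renders bright 2 px rings (≈190) around dark interiors (≈12)
  over a moderately bright interstitium (≈95), plus Gaussian pixel noise
  (σ = 4).
- **Songs** are harmonic stacks (6–10 harmonics, 1/k amplitude rolloff,
  truncated below the band top so filtering leaves levels intact) with
  constant or linearly swept f₀, cosine onset/offset ramps (5 ms), and
  syllable/gap durations snapped to the 0.5 ms frame grid. Source levels
  are set by scaling to the target RMS pressure.
- **Peptide tables** spread each protein's abundance over ≥ 4 peptides
  with Dirichlet ionization weights, log-normal between-animal variation
  (CV 0.15) shared within a pair, per-measurement technical noise
  (default CV 0.10), and per-protein fold changes applied to the treated
  member. The default panel is a ~20-protein syringeal profile with
  MYH13 at 92 % of the myosin pool and Histone H4 as the reference;
  red-blood-cell decoy rows are available for exclusion tests.
- **Keypeck logs** draw each peck Bernoulli(p, default 0.66) for the
  focal stimulus and map it to a key through the nightly-switched
  assignment over 4 days.

All generators are deterministic given (config, seed).

## Problem sizes and numerical choices

Validation runs use desk-scale problems chosen to give stable statistics:
200-fibre sections for segmentation recovery (count within 5 %, IoU
≥ 0.8), 10 × 300 fibres for typing recovery (fraction reported as the
mean over seeds, since a single Bernoulli draw at n = 300 has SD 0.027 —
comparable to the ±0.03 recovery band itself), 100 random twitch shapes
against the 1 MHz oracle, 20 harmonic stacks for Yin, 500 random
envelopes against the brute-force rule applier, 1000 null syllables for
type-I calibration, 50 generator seeds for fold-change recovery and 30
pair-ratios (10 seeds × 3 pairs) for the MyHC-pool ratio, and 100
simulated birds for preference power. Ties in the watershed are resolved
by scikit-image's deterministic scan order; histogram edges are anchored
at multiples of the bin width; dB conversions floor at −inf rather than
clipping; all f₀ gaps are NaN, never sentinel numbers.

## Known limitations

- The segmentation chain assumes reasonably continuous laminin borders;
  heavily broken borders would merge neighbours (the H-minima depth
  trades splitting against merging and may need retuning per dataset).
- Yin frames near syllable edges average over partially voiced windows;
  edge frames of fast sweeps are biased a few Hz inward. Per-syllable
  statistics therefore use the cleaned interior trace.
- The pre/post syllable tests treat motif iterations as independent
  samples, as in the published analysis; serial correlation within a
  session would inflate significance on real data.
- Proteomics operates strictly downstream of peptide identification;
  search-engine errors, shared-peptide inference beyond the MyHC flag and
  PSM-level FDR are out of scope.
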