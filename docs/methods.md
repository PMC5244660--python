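# Methods

## Pipeline overview

A channel pair runs through a fixed sequence:

1. **Background subtraction** per channel.  A Zack triangle threshold is
   computed on the full-range intensity histogram; the background
   estimate is the mean of pixels strictly below it, and this scalar
   (rounded) is subtracted with clamping at 0.  The triangle threshold
   is geometric: the bin between the histogram peak and the furthest
   nonempty bin that maximizes perpendicular distance to the line
   joining them.
2. **Intensity-range equalization**: each channel is independently
   min-max stretched to `[0, 2^bit_depth − 1]` so that gain and
   expression-level differences between the channels do not bias the
   object thresholds or the 2D histogram.  Pearson/Spearman/ICQ are
   affine-invariant, so this step changes them only through integer
   rounding (bounded by 0.01 in the test suite).
3. **Intensity-correlation suite** on the preprocessed pair: Pearson,
   Spearman (mid-ranks, average-rank ties), Manders M1/M2 at zero
   thresholds and at the automatic regression thresholds, Li's ICQ
   (zero deviation-products count as non-positive), the bisection
   threshold regression, and a 2D intensity histogram over the full
   bit-depth range.
4. **Object recognition** per channel: histogram thresholding
   (maximum-entropy by default), binary watershed to split touching
   objects, union ("combination") and intersection ("colocalization")
   masks, and particle analysis with a minimum area of 25 px.
5. **Correction**: every intensity coefficient is multiplied by the
   colocalization fraction `F = area(A∩B)/area(A∪B)` (areas after the
   particle filter).  The object-corrected Pearson coefficient is the
   primary read-out.

Undefined values (constant channels, empty masks, zero denominators)
propagate as NaN and reach the CSV as empty cells with a companion flag
column — a silent zero would fabricate "no colocalization".

## Thresholding algorithms

* **Triangle (background)** — as above; requires ≥ 2 distinct levels,
  otherwise the image is degenerate.
* **Maximum entropy (objects, default method)** — Kapur–Sahoo–Wong:
  the threshold maximizing the summed Shannon entropies of the
  below/above class distributions.  Suited to fine, sparse structures.
* **Intermeans / IsoData ("default" method)** — iterate
  `t ← (mean(≤t) + mean(>t))/2` from the midpoint of the nonempty range
  to a fixpoint.  Suited to spatially homogeneous staining over a dark
  background (e.g. a diffuse cytosolic fill); maximum entropy on such an
  image selects only the bright noise tail.
* **Manual** — a user-supplied intensity.

Foreground is always strict (`pixel > threshold`).  Histograms use one
bin per integer level for 8- and 12-bit data and 4096 equal-width bins
for 16-bit; a threshold expressed as a bin maps to the intensity at the
bin's upper edge.

## Bisection threshold regression

The automatic thresholds follow the Costes idea: fit the orthogonal
(total least squares) line `b = slope·a + intercept` over all pixels,
then find the largest `t_a` (with `t_b` on the line) such that the
strictly-below-both population is uncorrelated, by bisection on `t_a`
until the interval is below one intensity level.

The below-population correlation of genuinely uncorrelated pixels
fluctuates with standard error ≈ `1/√(n−3)`, so the acceptance test
"r ≤ 0" is applied with a 3·SE allowance; populations too small for
3·SE to resolve the sign (n ≲ 13) are never accepted.  Without this
allowance a single chance-positive evaluation below the true knee sends
the bisection into the noise floor.  If no threshold is acceptable, a
512-point scan returns the threshold minimizing |r| ("≤ 0, else
closest", switchable to "closest" only); if every candidate population
is absent or perfectly correlated (e.g. `b = a` exactly), the result is
flagged degenerate with thresholds at the channel minima.

## Object analysis conventions

* Connected components are 8-connected; coordinates are 0-based
  row-major.
* The watershed uses the Euclidean distance transform, regional maxima
  as seeds (maxima closer than 2 px merged by one-pixel bridging),
  and inserts 1-px background lines where basins meet; foreground never
  grows.  Connected ridge plateaus yield a single seed, so constant-
  width linear structures are not shredded.
* The 25-px minimum-area filter is inclusive (a 25-px component is
  kept) and is applied independently to mask A, mask B, their union and
  their intersection; in rare corner cases the filtered intersection
  can therefore exceed a filtered channel area by less than the minimum
  area.  The intersection mask is not re-watershedded.

## FRET model

Three filter cubes: DONOR (donor emission at donor excitation), rawFRET
(acceptor emission at donor excitation), ACCEPTOR (acceptor emission at
acceptor excitation).  Bleed-through factors are calibrated from
single-fluorophore references as ratios of background-subtracted masked
means (`df = ⟨rawFRET⟩/⟨DONOR⟩` on a donor-only sample, `af`
analogously); a pixelwise-median alternative is available behind a
flag.  The corrected FRET image is

    cFRET = rawFRET − DONOR·df − ACCEPTOR·af

kept signed for diagnostics; the apparent efficiency

    E = 1 − DONOR/(DONOR + max(cFRET, 0))

is evaluated over a signal mask (triangle threshold on DONOR OR
ACCEPTOR), with zero-donor pixels excluded.  Clamping negative cFRET
inside the efficiency avoids unphysical negative "efficiencies", at the
cost of a small positive bias of the mean at E = 0 under shot noise:
analytically ≈ `0.4·√(df + af + df² + af²)/SNR` (≈ 0.028 at SNR 10 for
df = 0.3, af = 0.1, ≈ 0.014 at SNR 20).  The non-interacting control
scenario in the tests is therefore imaged at SNR 20, which corresponds
to the line-averaged acquisition such calibration experiments use.
Efficiency is a per-pixel intensity ratio and is therefore normalized
for expression level by construction; no additional donor/acceptor
stoichiometry correction is applied.

## Synthetic scenes

The generator stands in for images of transfected cells.  All
randomness flows from one seed through one generator instance;
identical specs give bit-identical scenes.

* **Cell footprint**: a low-order (harmonics 2–5) Fourier perturbation
  of a disk covering ~80% of the field's shorter side, shared by both
  channels.
* **Diffuse background**: 40% of the object signal level, modulated by
  a shared smooth (σ = size/8 Gaussian-filtered) field in 0.6–1.4.
  This shared component — cell thickness and out-of-focus light — is
  deliberately what drives the false-positive intensity correlation
  between disjoint structures; at this level the disjoint-organelle
  scenes show classical Pearson r ≈ 0.5–0.85, matching the magnitudes
  the combined method is designed to suppress.  At substantially lower
  background (≤ 20% of signal) the false-positive effect weakens to
  r ≈ 0.3.
* **Scenarios**: `same_structure` (one ellipse set, independent
  per-object gains per channel), `mito_vs_er` (punctate blobs vs a
  disjoint dilated random-walk line network), `mito_vs_cytosol` (blobs
  vs diffuse footprint fill at 45% of signal), `overlap_sweep`
  (equal-radius non-touching disks, k shared + m per channel exclusive,
  chosen so k/(k+2m) matches the requested overlap within 0.01, else a
  generation error).
* **Noise**: Poisson shot noise calibrated so that SNR = √N at the
  object signal level, plus Gaussian read noise (σ = 2 levels), then
  integer quantization clipped to the bit depth.  Default SNR 10.
* **FRET triplets**: an unquenched donor field D₀ (diffuse fill, 0.7–
  1.3 modulation) gives DONOR = D₀(1−E), sensitized emission S = D₀·E,
  ACCEPTOR either stoichiometric with D₀ (fusion) or an independent
  fill (co-expression), and rawFRET = S + DONOR·df + ACCEPTOR·af.  No
  separate additive background is injected: diffuse cellular
  fluorescence is itself fluorophore emission and must obey the same
  bleed-through algebra.  In noise-free mode the channels stay
  real-valued, so the three-filter analysis inverts the construction
  exactly (recovery to 10⁻⁶ and better).

What the scenes do **not** model: PSF blur and optical resolution
limits, 3-D structure and z-stacks, spectral cross-excitation beyond
the linear df/af terms, multiple cells per field, photobleaching, and
camera fixed-pattern noise.  Passing tests therefore demonstrate the
correctness and discriminative behavior of the *analysis*, not the
segmentation difficulty of real micrographs; on real data the choice of
threshold algorithm (maximum entropy vs intermeans vs manual) remains
the user's responsibility, as it depends on staining morphology.

## Problem sizes and numerical choices

Synthetic scenes default to 256×256 px, 25 objects, 12-bit range —
large enough for stable coefficient statistics (≥ 65k pixels per
channel) while keeping a full scenario batch in seconds.  Coefficients
are computed in float64; the brute-force oracle comparisons in the test
suite demand agreement to 10⁻¹⁰.  Ties in the triangle and entropy
objectives resolve to the lower bin; the intermeans iteration caps at
1000 steps (fixpoint is reached in a handful).  CSV output writes
floats at 17 significant digits, making batch runs byte-reproducible.

## Known limitations

* The watershed merges seed maxima closer than 2 px by one-pixel
  bridging, which approximates but does not exactly reproduce ImageJ's
  binary watershed; heavily textured masks may split differently.
* Manders coefficients at the automatic thresholds inherit the
  regression's degeneracy cases (reported NaN when flagged).
* The colocalization fraction is area-based; very small structures
  below the 25-px particle cut-off do not contribute even when truly
  colocalizing.
* 12-bit acquisition stored in 16-bit containers must be declared
  (`--bit-depth 12`); the container depth is otherwise assumed.
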