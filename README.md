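# objcoloc

Object-corrected colocalization and three-filter sensitized-emission FRET
analysis for two-channel fluorescence microscopy.

## The problem

Whether two fluorescently labeled proteins occupy the same subcellular
structures is routinely scored with pixel-intensity correlation
coefficients — Pearson's *r*, Spearman's ρ, the Manders split
coefficients *M1*/*M2*, Li's intensity correlation quotient (ICQ).
These coefficients are prone to false positives: two markers residing in
*different* organelles of the same cell still correlate strongly,
because both channels share the cell's footprint, its diffuse
cytoplasmic background, and its overall intensity envelope.  A high
Pearson *r* between a mitochondrial marker and a cytosolic protein says
more about shared cell shape than about biology.

`objcoloc` implements a combined analysis that suppresses this artifact:
intensity-correlation coefficients are weighted by an object-based
colocalization area fraction.  Objects are segmented in each channel
(maximum-entropy, intermeans/IsoData, or manual thresholding, followed
by binary watershed separation and a 25-px minimum-area particle
filter), the two object masks are combined (union) and intersected, and

```
F = area(A ∩ B) / area(A ∪ B)            (colocalization fraction)
r_obj = r × F                            (object-corrected Pearson)
```

`r_obj` stays high only when the *structures* overlap, not merely the
cells.  Corrected variants of M1, M2 and the ICQ are emitted alongside.

Because colocalization — even complete colocalization — never proves
molecular interaction, the package also implements three-filter
sensitized-emission FRET:

```
df = rawFRET / DONOR          (donor-only reference)
af = rawFRET / ACCEPTOR       (acceptor-only reference)
cFRET = rawFRET − DONOR·df − ACCEPTOR·af
E = 1 − DONOR / (DONOR + cFRET)
```

A co-expressed, non-interacting donor/acceptor pair shows full
colocalization but `E ≈ 0`; a covalent donor-acceptor fusion shows the
same colocalization and a clearly positive `E`.

A seeded synthetic-scene generator renders two-channel images of
organelle-like structures (punctate mitochondria-like blobs, reticular
ER-like networks, diffuse cytosol fills) inside a random cell footprint
with shared diffuse background, Poisson-Gaussian noise, and known ground
truth — including FRET triplets built from known `df`, `af` and true
efficiency — so every stage of the pipeline is testable against
constructed truth.

## Worked example

```python
from objcoloc import SceneSpec, generate_pair, run_pair

for scenario in ("same_structure", "mito_vs_er"):
    pair, truth = generate_pair(SceneSpec(scenario=scenario, seed=1))
    res = run_pair(pair)
    print(f"{scenario:>16}: Pearson r = {res.correlation.pearson_r:.3f}, "
          f"coloc fraction = {res.objects.fraction:.3f}, "
          f"object-corrected r = {res.corrected_pearson:.3f}")
```

prints

```
  same_structure: Pearson r = 0.958, coloc fraction = 0.993, object-corrected r = 0.951
      mito_vs_er: Pearson r = 0.645, coloc fraction = 0.000, object-corrected r = 0.000
```

The same markers imaged in both channels keep `r_obj ≈ r`; disjoint
mitochondria-like vs ER-like structures still show a (spurious)
classical `r = 0.645`, but the object masks do not overlap, so the
corrected coefficient collapses to 0.

FRET distinguishes co-occurrence from interaction:

```python
from objcoloc import SceneSpec, generate_fret_triplet, run_fret, BleedThrough

triplet, _ = generate_fret_triplet(SceneSpec(seed=2, snr=20.0), true_df=0.3,
                                   true_af=0.1, true_efficiency=0.0,
                                   acceptor_mode="coexpression")
res = run_fret(triplet, bt=BleedThrough(df=0.3, af=0.1))
# co-expressed ECFP+EYFP analogue: mean FRET efficiency = 0.0145

triplet, _ = generate_fret_triplet(SceneSpec(seed=2), true_df=0.3,
                                   true_af=0.1, true_efficiency=0.3)
res = run_fret(triplet, bt=BleedThrough(df=0.3, af=0.1))
# donor-acceptor fusion analogue:  mean FRET efficiency = 0.2977
```

## Command line

Batch analysis of a folder of single-plane grayscale TIFF pairs
(channels matched by filename suffix):

```sh
objcoloc synth --scenario mito_vs_er --seed 1 --out data/
objcoloc run --dir data/ --suffix-a _C --suffix-b _Y \
             --threshold maxentropy --min-area 25 \
             --out results.csv --hist figures/ --overlays figures/
objcoloc fret --donor d.tif --rawfret f.tif --acceptor a.tif \
              --df 0.3 --af 0.1 --out fret.csv --eff-map eff.tif
```

`run` writes one CSV row per pair with the full coefficient suite
(classical and corrected), the regression thresholds, object counts and
areas, and a flag column; degenerate inputs are flagged rather than
aborting the batch.  Use `--bit-depth 12` for 12-bit data stored in
16-bit containers.

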