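# Methods

## Reference space and the relative-position field

The wall of a sectioned tubular graft is bounded by two operator-delineated
polylines: the adluminal (inner) and abluminal (outer) border. Both may be
closed contours (full cross-sections) or open chains (longitudinal strips);
open walls are closed by straight end-caps joining the border endpoints
(pairing chosen to minimize total cap length). The outer border is by
convention the most external continuous part of the graft, so adherent
connective tissue is excluded by construction.

Every grid cell whose center lies inside the wall polygon receives
`d1` (distance to the outer border curve), `d2` (distance to the inner
border curve) and `f = d1/(d1+d2)`. Distances are Euclidean point-to-curve
distances — the standard stereological reading of a two-distance relative
position — measured against the border polylines resampled at a quarter of
the grid spacing (a KD-tree query against the dense vertices), never
against a rasterized border mask; this removes quantization bias in `f`
near the borders. End-caps are *not* distance targets: `d1`/`d2` always
refer to the anatomical borders.

The three virtual sublayers are the level sets of `f`: outer `[0, 1/3)`,
middle `[1/3, 2/3)`, inner `[2/3, 1]`. The half-open convention gives
deterministic tie-breaking, with the extreme adluminal value assigned to
the inner layer. `f`-isolines and equal-local-thickness offset surfaces are
equivalent constructions wherever the wall is locally parallel; the
`f`-isoline form is used because it is well defined at any border
irregularity. Layer areas are cell counts × spacing²; at spacing ≤
thickness/100 the three areas sum to the polygonal wall area within 0.5%.

Wall thickness is estimated by resampling both borders at the analysis
spacing (default 2 µm), taking each resampled point's nearest distance to
the *opposite* border curve, and averaging the pooled distances of both
directions. Symmetric pooling is used because a one-sided nearest distance
is biased wherever the borders have unequal curvature (e.g. on an annulus,
inner→outer and outer→inner means differ systematically). For open walls,
resampled points within one nominal thickness (the median of the untrimmed
pool) of either cut end are discarded: near the open ends nearest distances
escape through the end-caps and would bias the mean downward.

## Nuclei-profile detection

Brightfield RGB is converted to optical density `OD = −log10(I/255)` per
channel and unmixed with the Ruifrok–Johnston hematoxylin/eosin/residual
stain vectors; only the hematoxylin channel is used, so DAB-counterstained
immunohistochemistry sections are handled identically. The OD map is
Gaussian-smoothed (default σ 0.75 µm), thresholded (default OD 0.25),
hole-filled, and split by a seeded watershed. Seeds are the local maxima of
the smoothed hematoxylin OD, thinned to a minimum Euclidean separation
(default 3 µm, below the typical nucleus-profile diameter); the watershed
floods the negated OD landscape. Intensity-based seeding is deliberate:
nucleus staining is densest at the profile center, so the OD landscape
separates laterally overlapping profiles whose union silhouette (and hence
whose distance transform) has a single maximum. Regions outside the
10–200 µm² plausible-profile-area band are discarded. Profiles closer than
the seed separation remain merged by design; resolving them is the role of
the manual curation step (`apply_manual_edits`), mirroring routine practice.
Manual additions are single points with zero recorded area; they count but
never enter area-weighted statistics.

Each profile's *decisive point* is its minimum-x pixel, ties broken by
maximum `f` (most adluminal), then minimum y. "Leftmost" is an image-frame
convention; the rule's purpose is unbiased edge handling — one well-defined
point per profile decides inclusion and sublayer — not anatomical meaning,
and assignments are invariant under common translations of image and
borders.

## Densities and aggregation

Per sublayer, `Q_A = Q/A` in mm⁻²; the whole-wall density is pooled
(ΣQ/Σ A), not the mean of the three layer densities — the two differ
whenever layer areas are unequal (annular walls). `f̄` is the arithmetic
mean of `f` at included decisive points; with zero included profiles it is
reported as missing, never as 0. Aggregation is micrograph → sample
(mean) → group (mean ± SEM across samples, SEM = sd/√n with n−1
denominator); averaging within samples first avoids pseudo-replication
from multiple fields per animal. Groups with one sample report a missing
SEM. No inferential statistics are computed.

## Synthetic ground truth

The generator emulates the remodeling states reported for electrospun PCL
aortic grafts in rat: `day10` (nominal thickness 744 µm, homogeneous
λ = 2500 mm⁻²) and `month6` (686 µm; per-third intensities inner 2976,
middle 2367, outer 1997 mm⁻²). These are generator parameters emulating
published group means — not a reproduction of the in-vivo data, whose
overdispersion (reported SDs of several hundred mm⁻²) a Poisson process
deliberately does not model. Preset geometry defaults to a longitudinal
strip (1800 µm) matching one analysed field of view at 1 µm/pixel on the
default 1616 × 1912 px canvas; an annular variant uses the graft's 825 µm
luminal radius. Border irregularity is a sinusoid on the outer border,
amplitude-limited so the borders cannot touch.

Nuclei are sampled as an inhomogeneous Poisson process by thinning:
candidates at the maximal intensity over the bounding box, kept with
probability λ(f)/λ_max using a grid-free `f` (0.5 µm border resampling), so
λ may depend continuously on depth. Rendering draws each nucleus with a
spherical-projection OD profile (absorbance ∝ chord length through a
stained sphere, drawn radius 3–5 µm, peak OD 0.7–1.0); overlapping profiles
combine by maximum, emulating laterally adjacent nuclei in a thin section
rather than axially stacked ones. The wall carries a flat eosin tint
(OD 0.15) and the camera adds Gaussian noise (σ 2 grey levels).

What passing tests show — and what they do not: the synthetic images have
clean stain vectors, shading-symmetric nuclei, no chromatin texture, no
tissue folds, no uneven illumination. They validate the geometry, counting
rules, calibration and the detector's splitting behaviour; they do not
certify detection accuracy on real histology, where threshold and area
defaults will need adjustment per staining batch and the curation step
matters more.

## Numerical choices and limitations

- Grid cells are pixel centers (0-based, y down); a cell is inside the wall
  iff its center is. Default grid spacing: the image pixel size, or 2 µm
  for point-set input.
- Analysis problem sizes: fields at 2 µm spacing, thickness at 2 µm border
  resampling, presets on the 1800 µm strip; halving either spacing changes
  thickness and areas by < 0.5%.
- Detection is fully deterministic (seed thinning resolves intensity ties
  by image order); all simulation randomness flows from one integer seed,
  and every pipeline output (CSV/JSON/TIFF/PNG) is byte-reproducible.
- Fully automatic detection under-counts dense fields by a few percent
  (profiles merged below the seed separation); the benchmark and preset
  recoveries in `scripts/acceptance.py` quantify this margin.
- The method is 2D: profile densities per section area, not number-weighted
  3D densities — section-thickness and shape/size biases are inherent to
  single-section counting and would require a volume (disector) probe,
  which is out of scope.
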