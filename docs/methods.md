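# Methods

This note documents the models, conventions and numerical choices behind
each analysis stage, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Imaging model and conventions

Images are 2D intensity grids with a physical pixel size (default
0.16 µm/px: a 100X objective on an EMCCD camera, so a 512-px field spans
~82 µm; the pixel size is acquisition-dependent and always
configurable). Coordinates are 0-based, x rightward, y downward;
physical quantities are in µm and seconds. The neurite ("cord") runs
horizontally with the anterior of the animal on the left, so leftward
motion is retrograde (toward the cell bodies) and rightward motion is
anterograde.

Puncta are modelled as isotropic 2D Gaussians evaluated at pixel centres
(no integration over the pixel area — at σ ≈ 1.6 px the difference is
negligible). The default σ = 0.25 µm gives a FWHM of 0.59 µm, inside the
0.5–0.7 µm range of diffraction-limited synaptic puncta. Noise is
additive Gaussian, chosen for analytic tractability over a Poisson/EMCCD
gain model; intensities are clipped at zero. The photobleached stretch of
cord used in transport imaging is rendered as background × 0.2 — the
bleach depth is not a measured quantity, only a contrast aid.

## Puncta quantification

Automatic thresholding defaults to Otsu's criterion (maximum
between-class variance over a 256-bin histogram, via scikit-image). A
percentile mode retains exactly the brightest fraction of pixels (ties
broken by intensity then flat index); it exists because colocalization
protocols often specify a pixel-fraction cutoff. Otsu on a constant
image is a degenerate histogram and raises rather than guessing.

Detection takes connected components of the thresholded mask
(8-connectivity default; 4 available), rejects components below
`min_area` = 4 px to suppress single-pixel noise, and reports
intensity-weighted centroids (better sub-pixel accuracy than geometric
centroids). Two spots merged into one component count once — an
inherent connected-component limitation. Density is count × 100 /
cord-length-µm. Integrated density sums the above-threshold
("detectable") pixels of a region; whether the same threshold as
detection is used is the caller's choice (`threshold` parameter), since
protocols differ.

## Colocalization

Tolerance method (neuronal cell bodies): each channel is min–max
rescaled to [0, 1] over its above-threshold pixels, so one tolerance
(default 0.1) applies across exposures; a pixel is colocalized iff above
threshold in both channels and |r₁ − r₂| ≤ tolerance. The fraction is
normalized to above-threshold channel-1 pixels, and the binary
colocalization mask is returned. An empty channel-1 mask yields an
undefined (NaN) fraction, flagged rather than raised. Channel thresholds
default to the top-5 % percentile rule; note that on sparse images this
retains background pixels beyond the true signal area and deflates the
fraction — the ground-truth recovery tests therefore use Otsu masks,
and both are configurable.

Pearson method (intestinal images): the sample correlation of the two
channels over a joint thresholded mask (≥ 3 px); a constant channel is
flagged undefined. Analysis is single-focal-plane. For intestinal data,
pixels flagged as autofluorescent (by spectral classification or a
DAPI-channel mask) can be excluded from both channels before either
statistic via the `exclude` argument.

Adjacency: fraction of A-puncta whose nearest B-centroid (KD-tree) is
within 1 µm — the "adjacent but not overlapping" organelle
relationship.

## Spectral unmixing

Lambda scans carry a 9-band emission spectrum per pixel (500–580 nm,
10 nm steps). Each pixel spectrum is decomposed as a non-negative
combination of two sum-normalized references — GFP (peak 510 nm) and
gut-granule autofluorescence (broad, red-shifted; the built-in default
peaks near 570 nm) — by closed-form two-variable non-negative least
squares (unconstrained 2×2 solve, then projection onto the better axis
when a coefficient goes negative). This is vectorized over pixels and
verified against `scipy.optimize.nnls` and a grid-search oracle in the
tests. Reference profiles can be measured from control data with
`build_reference_profile` (mean spectrum over ≥ 10 masked pixels). A
classify-then-zero mode (`classify_pixels`: nearest profile by
correlation) is provided for sensitivity analysis, since
profile-difference filtering can also be read as pixel classification.

Noise propagation: with sum-normalized references the design matrix
columns have norms ≈ 0.37/0.35, so per-band noise σ maps to an abundance
error of roughly 2.6–2.9 σ per component (exactly
σ·√diag((MᵀM)⁻¹)); a test verifies the estimator achieves this floor.
At σ = 0.01 the 99th-percentile absolute abundance error is therefore
≈ 0.07 — an information limit of the 9-band acquisition, not an
estimator deficiency.

## Kymograph tracking and transport metrics

A kymograph row is, per frame, the per-column maximum over the line
ROI's width (width 1 = plain line sampling). Particles are per-row local
maxima above a threshold, refined to sub-pixel positions by a
three-point parabolic fit — without refinement, the ±0.5 px
quantization of peak positions fragments the movement runs of slow
(~1 px/frame) vesicles and biases their velocities upward by ~5 %.
Linking is greedy nearest-neighbour: candidate (track, peak) pairs are
matched in order of increasing distance within `max_link_px` (default
8), ties broken by smaller column; unmatched peaks start new tracks.
Crossing particles may swap identities or split tracks at the crossing
(counted in `ambiguous_links` and visible as extra track segments); no
multi-hypothesis tracking is attempted.

Movement events (runs) are maximal stretches of successive
same-direction steps — steps below 0.5 px count as pauses — whose
cumulative displacement reaches `move_px` (default 3 px). Boundaries are
pauses, reversals, or the ends of the movie; run length is
|Δx| · pixel size. The mobile criterion ("displaced by at least three
pixels in successive time frames") is applied to this cumulative
same-direction displacement rather than to a single frame-to-frame
step: at 3.1 frames/s and 0.16 µm/px a vesicle at 1 µm/s advances only
~2 px/frame, so a strict per-step reading would class most physiological
vesicles as immobile; a 3-px single-frame jump still qualifies.
Stationary requires, in a track with no qualifying run, a spell of more
than `stationary_frames` (default 3) consecutive frames of sub-threshold
steps. Tracks meeting neither rule (length-1 tracks, short slow drift)
are excluded, with the reason recorded. A track formally satisfying both
rules — a long-immobile particle transiently dragged ≤ 2·`move_px` with
near-zero net displacement, as happens when another vesicle crosses a
stationary one — is classed stationary (dominant behaviour).

Direction is the sign of net displacement (decreasing x = retrograde);
mobile tracks with zero net displacement are "none". Track velocity is
the unweighted mean over events of run-length/duration. Flux is mobile
tracks per µm of region per minute (default region 18 µm, within the
conventional 15–20 µm window); since fragments from crossings each count
once, flux is an overestimate on busy cords in proportion to the
fragmentation rate. Reversal behaviour is reported both per-track
(fraction of mobile tracks containing both directions) and per-event,
since both conventions occur in practice.

## Statistics

Mean ± SEM uses the n−1 sample standard deviation. The 2×2 chi-square is
the closed form n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) with 1 df and no
continuity correction; degenerate marginals raise. t-tests are two-sided
and pooled (Student) by default, Welch optional. Multi-group comparisons
use one-way ANOVA with Bonferroni-corrected pairwise t-tests (all pairs,
or each-vs-reference); Bonferroni against a reference group is a
conservative stand-in for Dunnett's test — adjusted p-values are never
smaller than Dunnett's, so significance calls are never inflated.

## Rab6 sequence analysis

Pairwise global alignment is Needleman–Wunsch with affine gaps
(BLOSUM62, open 10, extend 0.5, via Biopython) rather than a ClustalW
multiple alignment: for pairwise identity/conservation statistics the
optimal pairwise alignment is deterministic and sufficient, and
reference-coordinate mapping absorbs any column-numbering differences.
Percent identity and percent conservation are computed over columns with
no gap in either sequence; "conserved" additionally counts substitutions
within the strong-similarity groups {ST, DE, KR, NQ, ILVM, FYW, AG}.
Both modes are exposed because published "conservation" figures rarely
state which was used.

Diagnostic classification maps Rab6A reference positions 63, 106 and 139
(1-based, ungapped) through the alignment and calls the subfamily from
the 106/139 pair: (T, S) → Rab6A-like, (S, T) → Rab6B-like, anything
else (including a gap) → ambiguous. Position 63 (V vs I) is reported but
deliberately excluded from the call because it partitions the family
differently from the 106/139 pair.

`simdata.make_rab6_family` generates a synthetic Rab6-like family for
desk-scale testing: random 210-residue proteins carrying the documented
subfamily structure (a Rab6A-like reference, a Rab6A'-like variant
differing at exactly three residues, Rab6B-like diagnostics, and a
RAB-6.1-like/RAB-6.2-like pair at 90 % conservation, substitutions drawn
outside the similarity groups). These are synthetic stand-ins — tests on
them exercise the alignment/classification code path, not the real
GenBank sequences, which users must fetch themselves.

## What the simulations do and do not show

The generators emulate: sparse Gaussian puncta on a linear neurite with
additive noise; two-channel images with a controlled shared-punctum
fraction and controlled centroid offsets; 9-band spectra as exact linear
mixtures plus noise; vesicles with constant speed, geometric pauses,
random reversals and field-of-view exit, over a bleached background.
They do not emulate: realistic PSFs or camera gain/EM noise, focal
drift, photobleaching decay over time, intensity heterogeneity between
vesicles, curved neurites, or 3D structure. Passing the recovery tests
therefore demonstrates correctness of the estimators under the stated
model, not robustness to every property of real micrographs.

Problem sizes in the test suite and acceptance script (10 movies × 5
vesicles × 150 frames per velocity condition; 512×64 px two-channel
images; 64×64 px lambda stacks) were chosen as the smallest sizes at
which the population statistics are stable; everything runs in seconds
on one CPU.

## Known limitations

- Greedy linking fragments tracks at crossings and can swap identities;
  flux counts fragments.
- Connected-component detection merges puncta closer than the threshold
  contour separation.
- The top-percentile channel threshold inflates sparse-image masks with
  background pixels (use Otsu for sparse fields).
- Two-endmember unmixing only; a third fluorophore violates the model
  and inflates residuals (inspect the residual image).
- Sub-pixel accuracy of kymograph positions (~0.1 px) relies on
  well-separated spots; overlapping spots bias the parabolic fit.
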