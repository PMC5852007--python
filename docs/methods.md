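# Methods

This note records the models implemented in `tagtrack`, the numerical
choices behind them, what the synthetic phantom does and does not emulate,
and the known limitations. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The correspondence cascade

A moving image is decomposed into a fixed hierarchy: 16×16 templates, each
containing four 8×8 segments, sixteen 4×4 chunks and sixty-four 2×2
windows, all row-major ordered and 0-based. Matching proceeds coarse to
fine with normalized cross-correlation (NCC):

1. each template is searched in the reference image around its own
   location (`template_search_radius`, default 8 px for standalone
   registration);
2. overlap sections of sizes 14, 12, 10 px refine the matched 16×16
   region towards each segment; a 6 px section bridges segment to chunk;
3. each child part is matched near its *expected* position — its offset
   relative to the matched parent — dilated by `overlap_margin`
   (default 2 px).

NCC is computed in three steps: raw cross-correlation of the mean-removed
part, local window sums/energies from precomputed running-sum (integral)
tables, and normalisation. Offsets where either patch has zero variance
are undefined under this normalisation; they are reported as γ = 0 with a
degenerate flag, so flat blood-pool and background windows never produce
NaN and are excluded from control points downstream.

### Overlap-section placement

The overlap sections of a parent are *aligned to contain the child*
currently being refined (clamped-centred on it), not centred in the
parent. With centred sections the final 10×10 region leaves an 8×8
segment with true relative offsets of −3 or +5 px, which no small search
margin can reach, while enlarging the margin re-admits tag-period aliases;
aligned sections guarantee the child's true position is always inside a
search window that stays smaller than one tag period. This is what makes
identity registration exact and rigid integer shifts exactly recoverable
at every non-degenerate window.

### Peak selection

The correlation maximum is taken over non-degenerate offsets, and offsets
whose γ lies within a tolerance of the maximum are treated as tied —
exact float equality is meaningless after running-sums arithmetic
(`1e-9`), and on smooth tag patterns small patches are under-constrained
along a tag line, where the correlation ridge is flat to about `1e-3`
(the aperture problem). Ties resolve towards the expected position, then
by smallest row, then smallest column; an all-degenerate map falls back
to the centre offset, flagged. Matching is integer-pixel throughout the
dense cascade.

### Tracking correspondences

Sequential tracking does not fit the transform on the dense 2×2 window
pairs. Measured on the contraction–twist phantom, single-pair match error
(RMS, px) is ~0.6 at template, ~0.5 at segment and chunk, and ~1.0 at
window level: a 2×2 patch carries almost no localisation information on a
smooth periodic pattern — its correlation is flat or deceptive along tag
lines, and wrong peaks win by margins no tie rule can absorb. The 8×8
segment is the smallest part spanning a full tag period in both axes,
hence the finest scale at which a displacement estimate is statistically
reliable. `tracking_correspondences` therefore emits one control point
per non-flat segment, with two refinements:

- **sub-pixel peak interpolation**: a parabola through γ at the peak and
  its two neighbours, per axis, skipped when the match is exact (peak at
  1 within rounding), so integer motion stays integer. Integer-quantised
  displacement fields have spatially *correlated* rounding errors that
  local blending cannot average away and that sequential composition
  accumulates linearly; sub-pixel peaks remove that bias at the source.
- **centre attribution**: block matching measures the displacement of the
  patch as a whole, so the estimate is attributed to the segment centre
  (origin attribution adds a systematic error of |∇u|·3.5 px).

The dense window set remains the output of `htm_correspondences` (and of
the `register` command); the segment-scale set is specifically the
transform-fitting input of `track_cycle`.

### Search radii and tag jumping

A periodic tag pattern has correlation rivals exactly one period from the
true match; under deformation the true peak's sub-pixel misalignment can
genuinely lose to an alias ("tag jumping", errors of one tag period).
The defence is geometric: keep the search radius below roughly half a tag
period minus the real displacement. Consecutive cardiac phases move by at
most a pixel or two, so `track_cycle` defaults to a 3 px template search
radius; standalone registration of arbitrary pairs keeps the wider 8 px
default and relies on image structure (annulus boundary) to disambiguate.

## The LWM transform

For each of N control points, degree-2 bivariate polynomials (6 monomials)
for the two target components are fitted over the point and its n−1
nearest neighbours — exactly interpolating at n = 6, least-squares for
n > 6. The default n = 12 stabilises conditioning; n < 6 is refused
because 6 quadratic coefficients cannot be determined from fewer points.
Coefficients are stored in a basis centred on each control point, which
keeps the local normal equations well-scaled. Fits whose squared design
condition exceeds 1e8 (near-collinear neighbourhoods) fall back to an
affine local fit with a logged warning.

Evaluation at (x, y) blends all polynomials whose support reaches the
point with the weight W(D) = 1 − 3D² + 2D³, D = distance/Dₙ, where Dₙ is
the distance from the polynomial's centre to its (n−1)-th nearest control
point. W(0) = 1, W(1) = 0 and W′ vanishes at both ends, so the blended
field is C¹-continuous. A query with zero total weight lies outside the
transform's support: the library raises an error naming the point; the
pipeline (`track_cycle`, CLI) instead extrapolates with the nearest
polynomial and logs how often it had to. No linear system over all N
points is ever assembled.

## Motion and strain

Tracking chains one registration per consecutive frame pair
(I₁→I₂→…→I_T); a 19-phase cycle is 18 registrations. Strain follows the
Eulerian (Almansi) convention: U = L − L₁ is the displacement referred to
the first frame, and ∂U is its gradient **with respect to current
(deformed) coordinates** — the only reading under which
F = (I − ∂U)⁻¹ and E = ½[I − (F Fᵀ)⁻¹] are the standard identities
(E = 0 for rigid motion; F = αI gives E = ½(1 − α⁻²)I).

∂U is estimated per point by a moving least-squares plane fit of U over
neighbouring tracked points' current positions (default radius 8 px)
rather than gridded finite differences, because tracked points deform off
lattice. Points with fewer than 3 non-collinear neighbours are flagged
and excluded from strain; (I − ∂U) with |det| < 1e-8 raises. E is
explicitly symmetrised to absorb inversion round-off.

E_rr and E_cc are the projections of E onto the unit vector from the LV
centroid to the point and its 90°-rotation. Points are assigned once
(from frame-0 positions) to the six 60° AHA sectors, counter-clockwise
from a configurable reference angle (half-open boundaries); regional
curves are unweighted means over each sector's valid points, with frame 0
identically zero and empty regions reported as NaN. Angles use the
anatomical convention: 0° towards +col, 90° towards −row ("up"). The
centroid and reference angle are configuration inputs — the package never
auto-segments the myocardium, and the sectors' anatomical anchoring is
the caller's responsibility on real data.

## The phantom

The phantom emulates an ECG-gated tagged short-axis acquisition: an
annular myocardium (default radii 20–36 px in a 128×128 frame at
1.48 mm/px, i.e. a ~5 cm outer diameter) carrying a multiplicative
cos²(πx/s)·cos²(πy/s) tag grid with s = 6 px ≈ 9 mm, on a dim uniform
background (0.05 vs tag contrast 0.9). Motions are closed-form maps about
the annulus centre — translation (linear ramp), rigid rotation, uniform
radial contraction, and contraction plus transmural twist (rotation
growing linearly from the inner to the outer radius) — modulated by the
cyclic profile sin²(πt/(T−1)), which peaks mid-cycle and closes the cycle.
Defaults: 19 frames, peak contraction α = 0.85 (analytic mid-wall
E_cc ≈ −0.19, within the −0.15 to −0.25 range typical of healthy human
LV), peak twist 8°.

Because every motion has an exact inverse, frames are rendered by
evaluating the analytic undeformed pattern (and the annulus membership
test) directly at the inverse-mapped pixel coordinates — continuous
sampling rather than interpolating a rasterised frame 0 — so the tags
move with the material exactly. Tag fading multiplies the contrast by a
per-frame decay factor; optional Gaussian noise is seeded per frame from
the study seed, making renders bit-identical across runs. Ground truth
comprises the forward map, its analytic Jacobian (verified against a
central-difference oracle in the tests), the Almansi strain, and 18
landmarks (3 transmural rings × 6 sector centres) with their exact
trajectories.

What the phantom does **not** emulate: MRI physics (k-space, SSFP signal,
receive-coil shading), through-plane motion, papillary muscles, tissue
texture between tag lines, and motion discontinuities at the
myocardium–blood interface. Passing its tests shows the pipeline is
correct and accurate under smooth, noise-controlled conditions; it does
not bound errors on clinical images, where fading, noise and untagged
structures degrade matching in ways only real data can measure.

## Evaluation harness

TRE is computed per frame as the RMSE over landmarks of the Euclidean
tracked-vs-true position error, in pixels and millimetres
(mm = px × pixel size); the aggregate mean ± sd pools the per-frame
values of frames 1..T−1 (frame 0 is the seeding frame and trivially
exact), and the report records what was pooled. The comparison harness
pairs two models' per-image errors, runs a paired t-test
(`scipy.stats.ttest_rel`), and reports model B's error as a percentage of
model A's plus the percentage reduction 100·(mean_A − mean_B)/mean_A.
Zero-variance paired differences (e.g. identical error vectors) make the
t statistic undefined; the report then carries the exact reduction with a
`degenerate` flag instead of infinities. Landmarks used for TRE must be
disjoint from the control points — guaranteed by construction here, since
control points live on the segment lattice and landmarks are arbitrary
myocardial positions.

## Problem sizes and defaults

The end-to-end validation runs the full study the generator defaults
describe: 19 frames of 128×128 px, tag spacing 6 px, no noise, no fading,
peak contraction 0.85 with 8° twist; landmark tracking uses the 18
ground-truth landmarks, regional strain uses 216 mid-wall seeds (3 rings
× 72). The NCC oracle comparison draws 200 random template/region pairs
with sizes 2–16; LWM reproduction uses 60 control points and 500 interior
queries. All randomness is seeded.

## Known limitations

- Correlation-based matching assumes the tag pattern survives between
  frames; heavy fading or noise (the generator can produce both) degrades
  the peak structure, and no regularisation exists to bridge unmatched
  areas — by design, as the method's premise is to avoid tunable
  regularisation.
- The search-radius/tag-period trade-off means very fast motion (more
  than ~half a tag period per frame) cannot be tracked reliably at the
  tracking default; such data needs denser temporal sampling.
- Strain near the myocardial edges mixes tissue and background windows;
  the degenerate-window exclusion mitigates but does not eliminate edge
  bias, and the MLS gradient needs a populated neighbourhood (≥3
  non-collinear points within 8 px).
- All analysis is 2D in-plane; through-plane motion and longitudinal
  strain are out of scope.
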