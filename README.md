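# tagtrack

Myocardial motion tracking and strain estimation for tagged cardiac MRI,
built around hierarchical template matching.

Tagged (SPAMM) MRI imprints a periodic intensity grid on heart muscle; the
grid deforms with the tissue, so tracking it through the short-axis frames
of a cardiac cycle yields patient-specific myocardial strain — a clinical
measure used in cardiomyopathy assessment, CRT lead placement and
chemotherapy cardiotoxicity monitoring. Benchmark non-rigid registration
(B-spline free-form deformation) needs per-image tuning of grid spacings,
regularisation weights and iteration counts; `tagtrack` implements an
alternative that needs none of that: dense point correspondence by a
coarse-to-fine normalized cross-correlation cascade, blended into a smooth
non-rigid transform by local weighted mean (LWM) interpolation.

## Method

**Correspondence.** A moving frame is tiled into 16×16 *templates*, split
into 8×8 *segments*, 4×4 *chunks* and 2×2 *windows*. Each template is
located in the reference frame by the maximum of the correlation
coefficient

γ(u,v) = Σ[(f − f̄₍ᵤᵥ₎)(p − p̄)] / {Σ(f − f̄₍ᵤᵥ₎)² Σ(p − p̄)²}^½,

computed with running-sum local statistics. Overlap layers (14, 12, 10 px
under a template; 6 px under a segment) shrink the reference search region
step by step, so each deeper part is matched inside an area smaller than
one tag period — which makes the search immune to the periodic pattern's
aliases. The top-left pixels of all windows and their matches form a dense,
uniform point correspondence (one pair per 2×2 px).

**Transform.** Given N control-point pairs, a degree-2 bivariate polynomial
is fitted through each point and its n−1 nearest neighbours (n = 12 by
default; n < 6 is refused as ill-conditioned). An arbitrary point maps to
the weighted mean of all local polynomials reaching it, with the compact
cubic weight W(D) = 1 − 3D² + 2D³ for D ≤ 1 (D = distance / Dₙ, Dₙ =
distance to the (n−1)-th nearest control point). No global system of
equations is ever solved.

**Motion and strain.** Sequential registration I₁→I₂→…→I_T advances
tracked material points through the cycle. With U = L − L₁ the
displacement referred to the first frame and ∂U its gradient in current
coordinates, F = (I − ∂U)⁻¹ and the Eulerian (Almansi) strain
E = ½[I − (F Fᵀ)⁻¹] — zero for any rigid motion. E is projected onto
radial/circumferential directions about the LV centroid (E_rr, E_cc) and
averaged in the six AHA sectors (Anterior, Anteroseptal, Inferoseptal,
Inferior, Inferolateral, Anterolateral).

**Validation.** A built-in synthetic phantom renders a tagged annulus
deformed by closed-form motion (translation, rotation, radial contraction,
contraction + transmural twist) with exact ground-truth trajectories and
strain, so every stage is testable without image downloads. Accuracy is
scored as target registration error (TRE): the RMSE between tracked and
true positions of 18 landmarks withheld from transform estimation.

## Worked example

```python
import tagtrack as tt

cfg = tt.PhantomConfig()            # 19-frame, 128x128 contraction + twist cycle
study = tt.generate_study(cfg)

traj = tt.track_cycle(study.frames, study.landmarks)
rep = tt.tre(traj, study.truth_trajectories, cfg.pixel_size_mm)
print(f"landmark TRE: {rep.mean_mm:.3f} +/- {rep.sd_mm:.3f} mm "
      f"(worst frame {rep.per_frame_px.max():.3f} px)")

seeds = tt.midwall_seeds(cfg)
straj = tt.track_cycle(study.frames, seeds)
regional = tt.regional_strain_curves(straj, cfg.centre, cfg.reference_angle)
print(f"peak circumferential strain: {regional.ecc.to_numpy().min():.3f}")
```

prints

```
landmark TRE: 0.450 +/- 0.189 mm (worst frame 0.458 px)
peak circumferential strain: -0.208
```

The 18 phantom landmarks are tracked through all 18 frame-pair
registrations with a worst-frame error under half a pixel (0.68 mm at the
1.48 mm clinical pixel scale this corresponds to; the per-frame mean is
0.45 mm), and the recovered peak E_cc of −0.21 matches the analytic peak
contraction of the phantom (α = 0.85 ⇒ E_cc = ½(1 − α⁻²) ≈ −0.19 at the
mid-wall, slightly amplified by the twist component). Healthy human LV
peak E_cc is typically −0.15 to −0.25, so the phantom operates in a
realistic regime.

The same pipeline runs from the shell:

```sh
tagtrack phantom --out study/ --frames 19
tagtrack register study/frame_000.png study/frame_001.png --out reg/
tagtrack track study/ --out trk/
tagtrack strain trk/trajectories.csv --out strain/ --centroid 63.5 63.5 --plot
tagtrack evaluate --tracked trk/trajectories.csv --truth truth.csv --out tre.json
```

## Layout

| module | contents |
| --- | --- |
| `tagtrack.image_parts` | template/segment/chunk/window decomposition, dense point sets |
| `tagtrack.ncc` | running-sums normalized cross-correlation, peak selection |
| `tagtrack.hierarchy` | the matching cascade; dense and tracking correspondences |
| `tagtrack.lwm` | local weighted mean transform (fit / apply / serialise) |
| `tagtrack.motion` | sequential tracking, strain tensors, AHA regional curves |
| `tagtrack.phantom` | synthetic tagged study generator with analytic truth |
| `tagtrack.evaluate` | TRE reports and paired model comparison |
| `tagtrack.cli` | `tagtrack` command-line interface and image I/O |

See `docs/methods.md` for the model details, parameter choices and known
limitations.
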