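# Methods

## The model

`endoepi` studies a single question: how much energy density a tumor
(epithelial) cell must spend to breach an endothelial vessel wall, and how
that cost changes when the cell first elongates along the vessel, as highly
metastatic breast lines (MDA-MB-231) are observed to do in 3D co-culture
with endothelial tubes.

### Geometry

Both cell types are modelled as prolate spheroids. An epithelial cell of
equivalent-sphere radius `r` deforms at constant volume, so its semi-axes
obey `a b² = r³`; a single aspect parameter `x = r/b ≥ 1` fixes the shape
(`b = r/x`, `a = r x²`, projected area `A = π r² x`). Shape in images is
summarised by circularity `C = 4πA/P²` with the perimeter `P` evaluated by
Ramanujan's first approximation,

    P = π (3(a + b) − √((3a + b)(a + 3b))).

Substituting the constant-volume axes gives a closed form `C(x)` that is
strictly decreasing from `C(1) = 1`, inverted numerically (Brent bracketed
root search on `x ∈ [1, 50]`, residual < 1e-12) wherever a measured inverse
circularity `C⁻¹` must be mapped back to a shape. The exact elliptic-integral
perimeter is used only as a test oracle: Ramanujan's form deviates from it by
well under 0.5% for aspect ratios up to 20, and keeping the approximate form
in the pipeline preserves bit-compatibility with the published formula.
Oblate inputs (`x < 1`, or a measured minor axis exceeding the major) are
rejected by the geometry layer; the table loader canonically sorts axes so
only genuinely invalid records fail.

### Breech energy

The cell crosses the wall at a junction between two endothelial cells, each
modelled as an incompressible neo-Hookean solid (`ν = 0.5`, shear modulus
`G = E/3`) under uniaxial compression. Per compressed cell the strain energy
density is

    W = (G/2)(λ² + 2/λ − 3) = (G/2) ε²(ε + 3)/(ε + 1),   λ = 1 + ε.

A round cell of diameter `d` compresses each neighbour (length `l`) by its
semi-minor axis: `ε_I = (d/2)/l`; with the default dimensions
(`d = 10.62 μm`, `l = 30.97 μm`) this is 0.1715. An elongated cell presents
a thinner profile, `ε_II = ε_I / x`. One metastatic cycle comprises
intravasation plus extravasation, doubling the cost.

**Prefactor modes.** The published formula carries a mechanical-efficiency
divisor (`W_br = E/(6 η_br) · ε²(ε+3)/(ε+1)` with a tabulated
`η_br = 0.15`), but evaluating it literally gives ≈1769 Pa for the round
cell where the published headline is 530 Pa. The headline numbers are
reproduced to ≤0.4% by the cycle total `W = 2 G ε²(ε+3)/(ε+1)` — two
crossings, two adjoining cells each storing `(G/2)f(ε)`, no efficiency
divisor — which is algebraically the verbatim form at `η_br = 0.5`. The
package therefore exposes both: `as_printed` (default, reproduces the
headline numbers) and `as_written` (verbatim formula, configurable
`η_br`); their documented equivalence at `η_br = 0.5` is tested.

### Deformation (actin) energy

Elongation requires breaking and re-forming actin bonds. The monomer
binding free energy is `ΔG_B = k_B T log(k_on M / k_off)`; the logarithm is
taken as natural (the statistical-mechanics convention for `k_B T` times a
rate-ratio log; base 10 is available via `log_base="10"`). The energy
density tied up in bonds is `W_act = (1 − f_act) N_A C_act ΔG_B` with
`C_act = 50 μM` stored as 0.05 mol m⁻³ (all energy densities are Pa =
J m⁻³), and polymerisation losses at efficiency `η_act` leave a net
`W_def = (1/η_act − 1) W_act`.

The relative f-actin content `f_act` is taken linear in the aspect excess,
`f_act(x) = clip(1 − γ(x − 1), 0, 1)`, a proxy for proportionality to
cross-sectional area (`A ∝ x`). The slope γ is derived at parameter
construction from the neutrophil benchmark *f_act = 0.8 at circularity
0.7* (γ ≈ 0.4955); it is exposed as a parameter because the calibration
data also quote a "relative diameter of 60%" anchor that is mutually
inconsistent with the circularity anchor under this geometry (a relative
diameter of 0.6 corresponds to C ≈ 0.48, not 0.7). With the circularity
anchor, `W_def` at `C⁻¹ = 1.68` is of order 10² Pa — not the "orders of
magnitude smaller" the headline analysis assumes, which would require a
broken-bond fraction below ~0.4%. `W_def` is therefore always computed
and reported as its own column, while headline comparisons (530 Pa,
239 Pa, 55% saving) use the breech term alone, which is the term those
published numbers match.

### Default parameters

| symbol | default | units | meaning |
|---|---|---|---|
| E | 10 000 | Pa | endothelial elastic modulus (AFM) |
| ν | 0.5 | – | Poisson ratio (incompressible) |
| η_br | 0.15 | – | breech efficiency (`as_written` only) |
| η_act | 0.15 | – | polymerisation efficiency |
| C_act | 0.05 | mol m⁻³ | f-actin concentration (50 μM) |
| M | 10 | μM | g-actin monomer concentration |
| k_on | 11.6 | μM⁻¹ s⁻¹ | polymerisation rate constant |
| k_off | 1 | s⁻¹ | depolymerisation rate constant |
| T | 310 | K | temperature |
| l | 30.97 | μm | endothelial cell length |
| d | 10.62 | μm | epithelial cell diameter |

## Interaction quantification

Two per-condition parameters:

* **EEA** `= Fl_on / Fl_total`: from tables, the on-vessel share of
  recorded fluorescence (falling back to the on-vessel cell-count fraction
  when fluorescence is absent); from images, the intensity share inside
  the vessel mask dilated by a configurable `contact_radius` (default
  1 px — "physical contact"), after constant background subtraction with
  negative residuals clipped.
* **Elongation** `= (C⁻¹_on − mean(C⁻¹_off)) / mean(C⁻¹_off)` per on-vessel
  cell, with the baseline mean computed per condition from its off-vessel
  cells (≥ 2 required). Negative values (rounder on the vessel) are valid.

Quartiles use linear interpolation (type 7); the source analysis never
states its method. Association quartiles are computed across images, a
choice the upstream description leaves open. The 2-parameter index places
each condition as the rectangle `[assoc Q1, Q3] × [elong Q1, Q3]`; pairwise
comparisons report rectangle intersection-over-union and centroid
distances (degenerate zero-area boxes compare equal when identical).

Note an intrinsic difference of estimands: when per-cell fluorescence is
proportional to projected area — which grows ∝ x at constant volume — the
fluorescence-weighted EEA exceeds the cell-count association probability
for conditions whose on-vessel cells elongate (by ≈0.02–0.03 for the
strongly elongating archetypes). The count fraction `n_on/n` is the
unbiased estimator of the association probability and is reported alongside.

## Synthetic co-cultures

The generator emulates the measured structure, not the microscopy: per
condition, on/off flags are Bernoulli(`p_on`); off-vessel baseline inverse
circularity is `1 + |N(0, 0.02)|` (round, "near 1.0"); on-vessel cells draw
an elongation from a shifted lognormal — long right tail matching the wide
metastatic elongation distributions — parameterised by its median and IQR
(shape σ = 0.75), then receive `C⁻¹ = (1 + elong) · baseline` converted to
axes at constant volume; diameters are `N(10.62, 2.37)` μm truncated
positive; fluorescence ∝ projected area.

Shipped archetypes fix the published medians: untreated MDA-MB-231
association/elongation 0.93/0.66, docetaxel 20 μM 0.58/0.16, docetaxel
50 μM 0.54/−0.0018, HMEC elongation −0.0026, and HMEC association 0.29
from the published 3.2-fold association contrast. The intermediate lines
(MCF-10A, SkBr3, MCF-7, MDA-MB-468) and **all** IQRs are not published;
they are fixed assumptions ordered by invasiveness and labelled as such
here. Parameter-recovery tests (n = 1000 per archetype, fixed seeds)
demand the count fraction within ±0.03 of `p_on` and the median elongation
within ±0.05.

Images are single-channel float canvases (512² default at 1.6 μm/px): one
smooth random tube (cubic-spline centreline; width drawn from the measured
endothelial dimensions, 30.97 ± 13.34 μm), on-vessel cells placed with
centres inside the tube and major axes along the local tangent, off-vessel
cells kept clear of the dilated mask (rejection placement, capped retries,
dropped cells logged and excluded from ground truth), all cells painted at
one per-pixel brightness so the image intensity split equals the
ground-truth fluorescence split, plus additive Gaussian read noise
(default σ = 1% of peak). No PSF, no z-structure, no photorealism: passing
tests show the quantification is self-consistent on idealised ellipse
renderings, not that it would segment or survive real micrographs — the
pipeline deliberately consumes masks and measurements, never raw images.

## Numerical choices and degenerate inputs

* Circularity inversion: Brent on [1, 50], `xtol = 1e-13`; forward/inverse
  round-trip holds to 1e-9 over `x ∈ [1, 10]`.
* `C⁻¹` of measured circles can land at `1 − 2e-16`; inverse circularity is
  floored at 1 and the elongation baseline check tolerates 1e-9.
* The elongation→`C⁻¹` map clamps below 1 with a logged warning rather than
  erroring, since slightly negative medians are physically meaningful.
* Strains are positive magnitudes (`λ = 1 + ε`); `ε ≥ 1` (full compression)
  and oblate aspects are domain errors, not silent fixes.
* Zero-IQR elongation specs degenerate to a point mass; an all-on condition
  has no baseline and is reported as a per-condition error while the run
  continues.

## Problem sizes

Tests run the recovery suite at n = 1000 cells per archetype and images at
512² with ≤ 40 cells; the energy profile is evaluated on grids of a few
hundred points. The whole suite completes in well under a minute.

## Known limitations

* The deformation-energy magnitude under the circularity-anchored f_act
  curve contradicts the "<3% of breech cost" claim of the source analysis
  (see above); γ is exposed rather than reverse-engineered.
* Archetype dispersions and intermediate-line parameters are assumptions.
* The vessel is a single tube; real co-cultures form networks with nodes.
* No significance testing: group comparisons are out of scope.
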