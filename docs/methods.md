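# Methods

## Scope and data model

The package evaluates proton plans from per-structure *cumulative* DVHs:
curves giving, for each dose level, the fraction of structure volume
receiving at least that dose. The curve is taken to be piecewise linear
between its knots ("volume receiving ≥ dose", matching clinical DVH exports);
all interpolated metrics (D_x%, D_vcc, V_dGy, mean dose) follow from that
convention. Where the curve has a plateau at the requested volume fraction,
`dose_at_relative_volume` returns the *highest* dose on the plateau — the
conservative choice for target-coverage reporting. Doses are absolute
Gy(RBE); a constant proton RBE of 1.1 is assumed to be already folded into
the inputs and is never rescaled. Percent-of-prescription values are derived
at report time from the fractionation scheme (default 50.4 Gy(RBE) in 28
fractions).

The differential form is obtained by differencing consecutive knots
(bin centre = edge midpoint); residual volume at the last knot closes into a
final bin at the last edge. With this convention the mean dose
`Σ v_i·c_i` equals the trapezoidal integral of the cumulative curve exactly,
which the tests use as an independent oracle.

## Radiobiological models

Every model first converts each bin's total course dose to EQD2 under the
linear-quadratic model, `EQD2 = D·(α/β + D/n_f)/(α/β + 2)`; the quadratic
inverse is also provided so uniform structures can be placed at an exact
EQD2. Tissue α/β: 4 Gy for the breast-tumour set; OAR parameter files do not
come with an α/β, so the registry defaults to 3 Gy (conventional
late-responding tissue), is configurable per structure, and is echoed in
every report's provenance block. A flag (`use_eqd2=False`) evaluates any
model on physical bin doses instead; this exists because published target
EUD tables in this setting are numerically consistent with physical-dose
EUDs (≈ 51 Gy(RBE)) rather than EQD2-converted ones (≈ 49 Gy(RBE) at
1.8 Gy/fraction), and users may need either convention. The default is the
EQD2 route.

* **EUD** — generalized power mean with exponent `a` (−7.2 for breast
  tumour). For negative `a`, zero-dose bins diverge; bins with EQD2 below a
  floor of 1e-3 Gy(RBE) are clamped to the floor with a warning, preserving a
  severe but finite cold-spot penalty. The mean is computed in log space
  (logsumexp), so exponents up to |a| ~ hundreds remain stable and the
  a → ±∞ limits approach the min/max bin dose as they should.
* **TCP (Poisson-LQ)** — closed D₅₀/γ form with slope constant `e·γ`
  (Källman convention; exposed as `slope_constant` since the D₅₀ fixed point
  holds under any reading). Bins combine as a `v_i`-weighted geometric
  product with reference volume 1 (relative DVHs); this is exactly the
  per-voxel product reduced onto binned data. The cell-number (N₀, α, β)
  form is not implemented — no parameters for it are shipped.
* **NTCP (LKB)** — probit in `D_eff = (Σ v_i·EQD2_i^{1/n})^n`, slope `m`.
  Φ is evaluated through `scipy.special.ndtr` (complementary-error-function
  route), so a near-zero heart dose (t ≈ −10) yields a well-defined ~1e-23
  probability rather than underflowing.

Fixed points used as anchors: TCP = 1/2 at uniform EQD2 = D₅₀ and
NTCP = 1/2 at D_eff = D₅₀, to machine precision; both are exercised by the
acceptance script.

## Gamma analysis

2D, reference-point-centric (loop over reference points, search the
evaluated plane), dose criterion as a percent of the reference global
maximum by default (local normalization behind a flag), low-dose threshold
relative to the same global maximum. The evaluated plane is bilinearly
interpolated on a polar-disc sub-grid of step DTA/`search_subdivision`
(default 10) within a radius of 3×DTA; that bounds the discretization error
on individual gamma values to roughly 0.05 in typical fields, but at very
steep dose gradients the error scales with the step, and comparisons across
*different* DTA values only obey strict criteria-monotonicity when run on a
matched step (set `search_subdivision` so DTA/subdivision coincides). Points
whose best match would fall outside the evaluated plane's extent receive the
best in-plane match; gamma near the plane boundary is therefore
conservative (inflated), as in physical QA.

## Robustness criterion

Worst-case evaluation over exactly eight labelled scenarios (range ±3.5%;
isocenter shifts ±X, ±Y, ±Z of 5 mm): the plan passes when every scenario's
total-target D95% is at least 90% of the prescription (45.36 Gy(RBE) at
50.4). The boundary is inclusive. Scenario construction is not part of this
stage — scenario DVHs come from the planning system or, for testing, from
the synthetic generator.

## Cohort statistics

Long-form metric tables (patient × variant × structure × metric) are
summarized per metric as mean plus sample SD (n−1) and/or min–max range,
with two-sided Mann-Whitney U p-values of each variant against a baseline
(default PB-PB, significance 0.05, no multiple-testing correction). The U
test switches between exact enumeration (both n ≤ 12, no ties) and the
normal approximation with tie and continuity correction; with a ten-patient
cohort the study-scale comparisons run exact. The n−1 SD convention
reproduces the published per-structure EUD summary SDs from their printed
per-patient values in 17 of 18 cells to half a printed decimal; the single
exception is consistent with the source computing SD before rounding the
per-patient values it printed (±0.05 input quantization can move a
ten-sample SD by ~0.05).

## Synthetic cohort generator

The generator's job is to reproduce the *summary statistics the analysis
consumes*, not anatomy. Per structure kind:

* targets — voxel doses from a truncated normal (0 to 115% of prescription).
  A requested (Dmean%, D95%) pair maps to (μ, σ) via σ = (Dmean − D95)/1.6449.
  Default variant calibration (Dmean, D95 in % of prescription):
  PB-PB (100.3, 97.5), PB-MC (97.6, 93.5), MC-MC (100.0, 97.1).
* heart / LAD / esophagus / contralateral lung — exponential low-dose bath at
  a per-patient mean drawn log-uniformly from the published cohort ranges
  (heart 0.12–1.07 Gy(RBE), etc.).
* ipsilateral lung — three-component mixture (in-field normal above 20 Gy,
  mid-dose uniform, exponential bath) hitting requested V20/V5
  (defaults 12.4% / 32.8% cohort means). The resulting LKB NTCP lands in the
  published 0.4–1.9% band.
* skin — a small hot fraction (5%) near prescription, upper-truncated at the
  requested D(0.03 cc) (default 100.2% of prescription), over a low-dose
  bath; carries a 500 cc absolute volume so the 0.03 cc metric is defined.

Patient-to-patient variation is a shared systematic coverage shift per
patient (σ = 1.0 pp, truncated at ±2σ) applied to all variants and target
substructures, plus small per-structure (0.3 pp) and per-variant (0.2 pp)
jitter; substructure EUDs within a patient are therefore strongly
correlated, an assumption, since true inter-structure correlations are not
recoverable from published summaries. The ±2σ truncation bounds the worst
nominal PB-MC D95 near 91.5%, which together with the scenario-degradation
cap below guarantees the universal robustness pass the generator is meant to
emulate.

Robustness scenarios act directly on DVHs (no 3D geometry exists): range
scenarios scale doses by ∓1% — a robustly optimised plan does not lose the
full ±3.5% range error as output dose — and shift scenarios combine a dose
loss drawn below 0.8% with a high-dose-tail erosion
(`cumulative^(1+ε)`, ε ≤ 0.02). Worst-case target D95 degradation is thereby
capped near 1.5 pp of prescription; all magnitudes are configuration.

Randomness: one master seed expands through named `SeedSequence` substreams
per (patient, variant, structure), so regenerating with more patients leaves
existing patients bit-identical, and cohort → files on disk is a pure
function of config + seed. Default problem sizes — 20 000 voxel samples per
structure, 0.05 Gy(RBE) dose bins — keep D95/D99 sampling and interpolation
error well below 0.1 pp while generating a full ten-patient cohort (three
variants + 24 scenario plans per patient) in under a second.

What the generator does **not** emulate: spatial dose structure, realistic
DVH shoulder shapes for OARs, inter-structure dose correlations beyond the
shared patient factor, or measurement noise in QA planes beyond rigid
shift + scale (+ optional white noise). Passing tests therefore demonstrate
the correctness and calibration of the *analysis*, not anatomical realism of
the inputs.

## Known limitations

* Constant RBE only; variable-RBE or LET-weighted response is out of scope.
* 2D gamma only; no detector-array geometry or absolute calibration.
* Radiobiological parameters are photon-derived literature values; the
  package reports which were used (provenance block) but does not fit them.
* DVH-level scenario perturbation cannot represent spatially heterogeneous
  range errors; it only bounds coverage degradation.
* DICOM RT import is not included; the plain-text DVH dialect is the I/O
  contract.
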