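# Methods

## Problem and pipeline

`cardrisk` compares the predicted risk of radiogenic late cardiac toxicity
between a photon and a proton treatment plan for the same patient.  Two
archetypal cases are shipped: a mediastinal Hodgkin-disease (HD) course
(36 Gy (RBE) in 18 fractions, heart largely in-field for both modalities)
and a craniospinal medulloblastoma (MB) course (23.4 Gy (RBE) in 13
fractions, heart receiving photon exit dose but almost no primary proton
dose).  The pipeline per structure (whole heart, pericardium, myocardium)
and modality is:

1. **Equivalent-dose bookkeeping.**  H_T = w̄R·D_T with w̄R = 1.1 for
   therapeutic protons (Gy (RBE)), 1.0 for photons.  The proton plan's
   stray neutron field contributes a mean equivalent dose
   H_stray = w̄R,n·D_stray with a patient-specific neutron weighting factor
   taken as configuration input.  The photon plan's out-of-field dose is
   already contained in the planned dose (the cardiac structures sit inside
   the region where the planning system is accurate), so no separate stray
   term is added for photons.
2. **Neutron shift.**  The neutron field inside the patient is spatially
   nearly uniform, so H_stray is added as a rigid shift of the proton
   primary DVH's dose axis.
3. **EQD2.**  Each DVH bin is corrected to the 2 Gy/fraction reference
   schedule, EQD2ᵢ = Dᵢ(dᵢ + α/β)/(2 + α/β) with dᵢ = Dᵢ/n_fractions and
   α/β = 3 Gy for cardiac late effects.
4. **Risk models.**  Linear relative risk RR = 1 + α₁D on the *total* mean
   equivalent dose (α₁ = 0.6 Gy⁻¹, 95% CI 0.2–2.5); relative-seriality and
   Lyman NTCP on the processed DVHs; ratios RRR = RR_p/RR_ph and
   RNTCP = NTCP_p/NTCP_ph.

## Model cores and numerical choices

**Relative seriality.**  P(D) = 2^(−exp[e·γ(1 − D/D₅₀)]) (so P(D₅₀) = ½ and
γ is the maximum normalised slope), combined as
NTCP = [1 − Πᵢ(1 − P(Dᵢ)ˢ)^{vᵢ}]^{1/s}.  The product is accumulated as
Σ vᵢ·log1p(−exp(s·log Pᵢ)) and inverted with `expm1`, so out-of-field organs
with per-bin probabilities far below double-precision underflow still yield
finite log-NTCP values.  For a uniform dose the formula reduces to P(D)
independently of s; this is asserted in tests.

**Lyman.**  NTCP = Φ(t), t = (D − TD₅₀(V))/(m·TD₅₀(V)),
TD₅₀(V) = TD₅₀(1)/Vⁿ.  The model is defined for a uniform partial-volume
dose; full DVHs are reduced with the Kutcher–Burman effective volume
V_eff = Σ vᵢ(Dᵢ/D_max)^{1/n} evaluated at the maximum DVH dose — the
standard companion reduction, chosen over gEUD-at-full-volume because it
reproduces the exact partial-volume formula for two-level DVHs.  Φ is the
error-function-based normal CDF in double precision; tail ratios use
`logcdf`.

**Ratios and floors.**  RNTCP on the probability scale treats values below
1e-12 as zero: both-zero pairs report RNTCP = 0 (the convention of the
clinical risk tables), a vanishing photon NTCP alone reports no finite
ratio.  Sensitivity sweeps instead form ratios in log space
(exp(log NTCP_p − log NTCP_ph)), which keeps the parameter trends strictly
monotone even where both probabilities are ~1e-100; probabilities below
~1e-300 (double-precision underflow) are reported as 0.

**Presentation rounding.**  Reports round half-up at 2 decimals after
snapping away sub-ULP float noise (so a value that is mathematically 2.175
prints as 2.18); all internal comparisons are full precision.  When a case
config carries the tabulated total equivalent doses (quoted to 2 decimals,
as in the published dose table), the RR computation at nominal neutron
scaling uses those tabulated values — the table is the input — while any
sweep over the neutron scale recomputes totals from components at full
precision, keeping the RRR-vs-scale curve continuous and strictly
increasing with its closed-form unity crossing
f* = (D_photon − w̄R·D_primary)/H_stray.

**EQD2 ordering.**  The LQ correction is applied *after* the neutron shift,
i.e. to the Sv-valued axis.  Correcting an equivalent-dose axis with a
model formulated for absorbed dose is an approximation (the alternative —
correcting only the primary component — is available by reordering the
`radiobiology` calls); for the shipped cases the neutron shift is ≲ 0.7 Sv,
where the per-bin correction factor differs from unity by < 15% of the
shift itself.

**Per-bin fraction dose.**  dᵢ = Dᵢ/n_fractions assumes every subvolume
receives its total bin dose evenly over all fractions — the standard
DVH-wise LQ practice.  After the (non-linear) correction the bin grid is no
longer uniform; the DVH container therefore allows a non-uniform,
strictly increasing dose axis (`bin_width=None`).

## Parameters

| Parameter | Default | Units | Meaning / rationale |
|---|---|---|---|
| α₁ (CI) | 0.6 (0.2–2.5) | Gy⁻¹ | linear excess-RR coefficient for cardiac mortality from childhood-cancer survivor data |
| α/β | 3 | Gy | cardiac late-effect LQ ratio |
| w̄R proton / photon | 1.1 / 1.0 | — | therapeutic-field weighting (Gy (RBE) convention) |
| w̄R neutron (HD / MB) | ≈ 8.46 / 8.13 | — | *reconstructed* from the tabulated stray equivalent/absorbed dose ratios (0.66/0.078, 0.26/0.032); the underlying Monte Carlo values are unpublished, so these are config inputs, not authoritative |
| fractions (HD / MB) | 18 / 13 | — | prescription schedules of the two courses |
| bin width | 0.05 | Gy | synthetic DVH export resolution |
| NTCP sets | 7 bundled | — | pericardium: Lyman (48/0.35/0.1 historical; 50.6/0.64/0.13 esophagus); myocardium and whole heart: relative seriality (52.2/1.25/0.87 and 70.3/0.96/1; 52.3/1.28/1, 63.3/0.93/1, 70.3/0.96/1) |
| RNTCP zero floor | 1e-12 | — | probability below which a ratio is not formed |

Only Hodgkin-derived NTCP parameter sets report *absolute* NTCP values for
the HD case; all sets participate in ratios.  For the MB patient no
MB-specific dose-response data exist, so only RNTCP is meaningful and the
plausible-range sweeps (D₅₀ ∈ [40, 80] Gy, n ∈ [0.2, 1], m ∈ [0.05, 0.5],
γ ∈ [0.8, 1.5], s ∈ [0.5, 1]) bracket the parameter uncertainty.

## Synthetic data: what it emulates and what it does not

The patients' planning-system DVHs are not publicly deposited; the
generator reproduces their *summary statistics*, not their shapes:

- Mean doses per structure/modality equal the published dose table exactly
  (enforced by a final affine rescale of the dose axis, keeping generation
  deterministic; a seeded ±2% jitter on shape location/scale makes distinct
  seeds produce distinct histograms).
- HD DVHs are bimodal (a hot in-field component at ~33–34 Gy holding 25–30%
  of the volume plus a colder scatter component, logistic spread 1.5 Gy) —
  enough heterogeneity for serial-organ NTCP behaviour in the percent
  range.  MB photon DVHs are broad unimodal exit-dose distributions
  (spread 2.5 Gy); MB proton DVHs are near zero, with > 95% of the heart
  volume below 1 Gy.
- Contour-uncertainty variants mix each shell structure's DVH with its
  interior neighbour's (weights 1/f and 1 − 1/f for an f-times-thicker
  shell), since no imaging exists at the DVH level.

Consequently: RR, RRR, the equivalent-dose totals and the
neutron-scaling/crossing results are *exact* reproductions of the mean-dose
arithmetic; absolute NTCP values and RNTCP magnitudes are order-of-magnitude
stand-ins (e.g. HD whole-heart NTCP ~1–2% vs the published ~2%; MB ratios
10⁻⁵–10⁻¹, all ≪ 1).  Passing tests therefore demonstrate the pipeline's
correctness and the robustness of the *qualitative* findings (MB RNTCP < 1
across the full parameter grid; pericardium RNTCP increasing in m;
myocardium/whole-heart RNTCP decreasing in γ), not agreement of absolute
complication probabilities with the patients' actual anatomy.  The fine
structure of the real DVHs can even flip the sign of an HD RNTCP relative
to unity (proton and photon in-field doses are close), so HD RNTCP values
from the synthetic fixtures should be read as "near unity", no more.

## Degenerate inputs and tie-breaks

- A zero-dose DVH has Lyman NTCP Φ(−1/m) via the D_max = 0 convention
  (V_eff = 1, D = 0) and relative-seriality NTCP P(0)-based.
- `bin_width` is required to convert a single-bin DVH to cumulative form
  (edges are otherwise undefined).
- Bin *centers* carry the dose value throughout (the export convention of
  the histogram source is not specified; centers make mean-dose arithmetic
  exact for symmetric bins).
- Rebinning splits volume proportionally to bin overlap (conservative, so
  total volume is conserved and the mean moves by less than one source bin
  width).
- Grid points violating model validity (s ≤ 0, m ≤ 0, V = 0) are skipped
  with a warning in sweeps and rejected with `ValueError` elsewhere.

## Problem sizes

The shipped analyses are small by construction: 3 structures × 2 modalities
per case, DVHs of ~500–900 bins at 0.05 Gy resolution, parameter grids of
27–36 points per structure (the published surfaces use comparable 3–5-value
axes per parameter).  The full test suite and the acceptance script each
run in well under a minute on one core.

## Known limitations

- No DICOM/TPS import; DVHs enter via the plain-text format only.
- Neutron w̄R values are reconstructed ratios, not transport-calculated
  spectra; energy dependence is out of scope.
- The Lyman DVH reduction choice (effective volume vs gEUD vs mean dose)
  cannot be disambiguated against the original study without its DVHs; the
  reduction is configurable in code and the choice is documented above.
- NTCP here supports *relative* comparison of plans, not absolute outcome
  prediction; chemotherapy interaction and non-cardiac late effects are out
  of scope.
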