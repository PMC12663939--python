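# Methods

This document records the model derivation, the assumptions behind it,
the shipped parameter defaults and how they were calibrated, the design
of the synthetic data generators, and the numerical choices that affect
results.

## 1. Thermodynamic relations

**Kelvin (psychrometric) relation.** Liquid water at potential ψ (MPa)
equilibrates with vapor at fractional relative humidity

h = exp(ψ·V̄w / (R·T)),

with V̄w = 1.805×10⁻⁵ m³ mol⁻¹ and R = 8.314 J mol⁻¹ K⁻¹. The scale
R·T/V̄w is ≈ 137.3 MPa at 25 °C and ≈ 141.0 MPa at the model's default
leaf temperature of 306.15 K (33 °C): tens of MPa of liquid-phase tension
correspond to only a few percent of humidity depression, which is why
substomatal undersaturation of a few percent implies potentials near
−10 MPa. Small positive ψ up to +0.1 MPa is tolerated with a warning
(measurement noise); larger values raise.

**Saturation vapor pressure.** Tetens' formula (default) or Buck's
variant, valid over (243, 333) K; they agree within 1% in that range.
Mole fractions are w = e/P with P in kPa.

**Air state.** Campaigns control (VPD, T_leaf), so
w_a = (e_sat(T_leaf) − VPD)/P. A VPD of 4.82 kPa (the top of the
campaign range) requires e_sat(T_leaf) > 4.82 kPa, i.e. T_leaf ≳ 32.5 °C;
the synthetic campaign therefore runs at 33 °C and the model default
temperature is 306.15 K. Infeasible (VPD, T) pairs are rejected.

## 2. Gas-exchange analytics

For one record with adaxial/abaxial transpiration E_ad, E_ab
(mmol m⁻² s⁻¹), xylem water potential ψ_xyl and substomatal-cavity
potential ψ_ssc (from the nanoreporter), at leaf temperature T and
pressure P:

- w_sat = e_sat(T)/P; w_xyl = w_sat·h(ψ_xyl); w_ssc = w_sat·h(ψ_ssc);
  w_a from VPD.
- **OXZ conductance** g_oxz = (E_ad + E_ab)/(w_xyl − w_ssc). A
  non-positive driving force yields NaN and a logged warning (flagged
  record), never an exception.
- **Stomatal conductance with measured interior humidity**
  g_s = E·(1 − (w_i + w_a)/2)/(w_i − w_a) with w_i = w_ssc; the
  (1 − (w_i+w_a)/2) factor is the standard bulk-flow (Stefan flow)
  correction and can be disabled.
- **Saturation-assuming (Gaastra) estimate** g_s_sat = E/(w_sat − w_a),
  deliberately without the bulk-flow factor: it is the conventional
  estimate being critiqued.
- **Saturation-deficit phenotypes**
  - δw = (w_sat − w_ssc)/(w_sat − w_a)
  - δg_s = (g_s − g_s_sat)/g_s
  - δiWUE = 1 − E/E_sat with E_sat = g_s·(w_sat − w_a) (flux
    convention, default), or equivalently 1 − g_s_sat/g_s under the
    conductance convention. Both are positive under interior
    undersaturation and equal for the same record when the bulk-flow
    correction is off.

**Identity.** With the bulk-flow correction disabled, δg_s = δw exactly:
g_s = E/(w_i − w_a) and g_s_sat = E/(w_sat − w_a) give
(g_s − g_s_sat)/g_s = (w_sat − w_i)/(w_sat − w_a). The unit-tested
two-node identity δw = r/(1 + r) with r = g_s/g_oxz (for a xylem at
saturation) makes the conductance ratio the mechanistic predictor of all
three phenotypes.

**Binning.** Campaign summaries bin on stress magnitude −ψ_xyl with
right-closed intervals, so a record exactly on a shared edge (e.g.
ψ_xyl = −0.4) goes to the *lower-stress* bin ("0 to −0.4"). VPD bins are
right-closed on VPD itself. Empty bins are reported with n = 0.

## 3. Two-compartment transport model

### 3.1 Structure

The leaf thickness L (default 250 µm) is divided into n cell-centered
finite volumes. Each layer i carries two unknowns: the symplasmic
(cell-to-cell) potential ψ_cc,i and the apoplasmic/vapor potential
ψ_apo,i. The discrete balance equations are:

- **Axial symplasmic conduction** between adjacent layers with face
  conductance k_cc/Δz (mol m⁻² s⁻¹ MPa⁻¹ per leaf area).
- **Axial apoplasmic/vapor conduction** with face conductance k_vap/Δz.
  k_vap lumps wall-film liquid flow and intercellular vapor diffusion
  into one effective potential-driven conductivity.
- **Trans-membrane exchange** in each layer: a_int·κ_mem·Δz·(ψ_cc,i −
  ψ_apo,i), where a_int is membrane area per tissue volume and κ_mem the
  membrane conductance per membrane area.
- **Xylem boundary**: ψ_cc is Dirichlet-pinned to ψ_xyl at the layer
  containing the xylem plane (default mid-depth). This abstracts the
  (relatively high-conductance) xylem itself out of the OXZ problem.
- **Epidermal boundaries**: no-flux for the symplasm; stomatal Robin
  conditions for the apoplasm at both faces, E_surf = g_s·(w(ψ_surf) −
  w_a), with the surface humidity linearized (below). g_s = 0 encodes a
  taped surface.

### 3.2 Linearization

Within the solver the Kelvin relation is linearized, w(ψ) ≈ w_sat·(1 +
ψ·V̄w/RT) = w_sat + β·ψ with β = w_sat·V̄w/(R·T) ("mole fraction per
MPa", the unit bridge between potential-driven and mole-fraction-driven
conductances). The linearization errs by < 0.4% in h down to −10 MPa and
~4% at −35 MPa; all *reported* humidities, mole fractions and g_oxz use
the exact exponential applied to the solved potentials. Because κ_mem is
evaluated at the *upstream* ψ_xyl (a quasi-steady assumption — the
membrane state follows plant-level stress, not the local apoplasm), the
whole system is linear and solved with one sparse direct solve
(`scipy.sparse.linalg.spsolve`). Mass conservation (total membrane
exchange = total transpiration) holds to machine precision by
construction and is asserted to 10⁻⁹ in the tests.

With n = 1 the discretization reduces exactly (in the linearized
mole-fraction space) to the independent series closed form
w_ssc = (g_oxz·w_xyl + g_s·w_a)/(g_oxz + g_s) — the solver's oracle test.

### 3.3 Membrane law

κ_mem(ψ) = κ_min + (κ_max − κ_min)/(1 + exp((ψ50 − ψ)/s)), a saturating
loss of plasma-membrane water permeability with stress, bounded between
protoplast-plausible extremes; requires κ_max > κ_min and s > 0. The
sigmoid argument is clipped at ±500 to avoid overflow.

### 3.4 Candidate architectures (scenarios)

1. **uniform_membrane** (preferred): κ_mem(ψ_xyl) applied at every
   symplasm–apoplasm interface. Produces a large, distributed
   symplasm–apoplasm disequilibrium while mesophyll ψ_cc stays near
   ψ_xyl (turgor maintained).
2. **symplasm_conductance**: membranes stay at κ_max; the axial
   cell-to-cell conductivity is scaled by the normalized sigmoid
   instead. The high-permeability membranes keep the apoplasm
   near-equilibrated with the symplasm (max disequilibrium < 1 MPa), so
   this architecture cannot produce deep substomatal undersaturation.
3. **wall_air_layer**: κ_mem in series with the vapor conductance of a
   200 nm air-filled wall layer (Fick diffusion, D = 2.6×10⁻⁵ m² s⁻¹).
   The layer's conductance is orders of magnitude larger than the
   membranes', so predictions are indistinguishable (< 0.1%) from the
   uniform scenario — an air gap is not a viable alternative
   explanation of the resistance.
4. **bundle_sheath_only**: the loss is confined to the xylem-adjacent
   (bundle-sheath) layer — a membrane surface resistance
   1/(κ_mem·a_bs) in series at that layer's cell-to-cell faces, with
   a_bs the bundle-sheath membrane area crossed per unit leaf area per
   side (default 2), mesophyll membranes at κ_max. To sustain the
   observed fluxes, mesophyll ψ_cc must then fall tens of MPa below the
   turgor loss point — contradicted by observed turgor maintenance,
   hence the rejected architecture. `scenario_compare` reports the
   `turgor_ok` flag for exactly this discrimination.

### 3.5 Stomatal closure schedule

`gs_closure_schedule` is piecewise linear: fully open (180 mmol m⁻² s⁻¹)
above ψ_xyl = −1.5 MPa, declining threefold to 60 by −1.8 MPa, flat
below. Coupled to the response curves, it reproduces the non-monotone
substomatal-humidity signature: h_ssc is deepest at intermediate stress
and *recovers* once stomata close near the turgor loss point.

## 4. Parameter defaults and their calibration

| Parameter | Value | Units | Rationale |
|---|---|---|---|
| T_leaf (default) | 306.15 | K | feasibility of VPD up to 4.82 kPa; warm-greenhouse leaf |
| P | 101.325 | kPa | standard pressure |
| turgor loss point | −2.0 | MPa | maize leaf |
| L (thickness) | 2.5×10⁻⁴ | m | maize leaf lamina |
| n_layers | 50 | — | < 2% discretization error (see §6) |
| xylem_position | 0.5 | — | mid-depth vascular plane |
| k_cc | 1.0×10⁻⁵ | mol m⁻¹ s⁻¹ MPa⁻¹ | calibrated (below) |
| k_vap | 6.3×10⁻⁷ | mol m⁻¹ s⁻¹ MPa⁻¹ | calibrated (below) |
| a_int | 1×10⁵ | m² m⁻³ | mesophyll membrane area density |
| κ_max | 1.06×10⁻³ | mol m⁻² s⁻¹ MPa⁻¹ | calibrated (below) |
| κ_min | 1.30×10⁻⁵ | mol m⁻² s⁻¹ MPa⁻¹ | calibrated (below) |
| ψ50 | −0.10 | MPa | calibrated (below) |
| s (slope) | 0.167 | MPa | calibrated (below) |
| κ bounds (fit) | [10⁻⁶, 10⁻²] | mol m⁻² s⁻¹ MPa⁻¹ | protoplast-plausible bracket |

**Calibration of the defaults.** The package's central fitting procedure
is "adjust the membrane law so the forward model reproduces measured
macroscopic behavior"; the shipped defaults were produced by exactly that
procedure, run once against four macroscopic anchors that characterize
the phenomenon the package models: (i) substomatal h ≈ 0.92 (ψ_ssc ≈
−12 MPa) at ψ_xyl = −0.85 MPa, VPD 4.2 kPa, g_s = 180 mmol m⁻² s⁻¹;
(ii) g_s/g_oxz ≈ 0.01 at ψ_xyl = −0.2 MPa; (iii) a peak ratio ≈ 0.15
under stress; (iv) a ≈ 25-fold decline of g_oxz between −0.2 and
−1.8 MPa. The calibration minimized the squared log-deviation of the
model from these anchors over (κ_max, κ_min, ψ50, s, k_cc, k_vap) by
differential evolution, with κ constrained to the protoplast bracket.
The achieved defaults give ψ_ssc = −11.97 MPa, ratio(−0.2) = 0.0086,
peak ratio = 0.178 and a 21.4-fold decline — all within the tolerances
the acceptance tests assert. No test-suite outcome fed back into this
calibration; the anchors were fixed first.

## 5. Synthetic data

**Campaign.** 87 measurements over 37 plants (round-robin over three
"days", so every plant has 1–3 records). ψ_xyl ~ U(−2, 0) MPa and VPD ~
U(2.66, 4.82) kPa, independent. Each record is a full forward solve with
the closure schedule; assimilation follows a saturating
A = 40·g_s/(g_s + 100) µmol m⁻² s⁻¹. Noise: unit-median lognormal with
5% relative sd on E_ad, E_ab, A; additive Gaussian (sd 0.15 MPa) on both
potentials, clipped to preserve ψ_ssc < ψ_xyl ≤ 0 (an inverted pair
would be rejected by the analytics rather than silently averaged).
Ground-truth (`true_*`) columns ride along as extra columns. Randomness
derives from `np.random.SeedSequence(seed).spawn`, so design and noise
streams are independent and runs are byte-reproducible.

Known limitations: plants share identical physiology (no plant-level
random effects); drivers are uncorrelated although field VPD and stress
co-vary; temperature is fixed.

**Images.** 256×256 synthetic FRET frames: an autofluorescence channel
with bright cells (smooth disks when turgid; shrunken six-lobed
outlines, r(θ) = 0.72·r·(1 + 0.20·sin(6θ + φ)), when not) over a dim
background with dark elliptical substomatal cavities; and a ζ map from a
known ψ field (uniform/Gaussian/bimodal) through the calibration curve,
plus optional pixel noise. The ground truth (ψ field, wall mask, cell
labels, histogram mode) is returned alongside.

The shipped `DEFAULT_CALIBRATION` (logistic between ζ 0.20–0.70 with
midpoint −8 MPa over [−20, 0]) is a *synthetic placeholder* for tests and
demos, not a physiological calibration; real analyses should load a
measured curve via `CalibrationCurve.from_table`.

## 6. Numerical choices

- **Discretization error.** g_oxz at the default conditions changes by
  < 2% from n = 50 to n = 200; the tests assert convergence under
  refinement. n = 50 balances accuracy against the per-solve cost that
  dominates fitting.
- **Fitting.** Bounded trust-region least squares on log g_oxz (the
  conductance spans > 1 decade; the log loss weights plateau and decline
  comparably), κ parameterized in log10, 5 seeded multistarts (ties
  broken by loss then κ_max), rows sorted internally for order
  invariance, optional `se` column as relative weights. A fitted
  κ_max/κ_min < 1.5 flags the sigmoid as unidentifiable (flat data).
  Requires ≥ 4 points spanning ≥ 1 MPa. Noise-free synthetic data are
  recovered to ~10⁻⁴ relative; 5% noise leaves ψ50 within ~0.03 MPa.
- **Circularity.** 4πA/P² on a sub-pixel contour: the binary mask is
  padded, smoothed with a Gaussian (σ = 1 px) and contoured at 0.5
  (marching squares); the perimeter is the polyline length and the area
  the shoelace area *of the same contour*. Raw pixel-boundary perimeters
  bias circularity (disk ≈ 0.91, square ≈ 0.89); the smoothed contour
  gives disk ≈ 0.99 and square ≈ 0.82 (ideal π/4 ≈ 0.785) and is
  scale-invariant to < 2%. Values are capped at 1.
- **Segmentation.** Otsu threshold → hole filling → component-size
  filter → distance-transform watershed seeded at h-maxima (h = 2) →
  border-touching labels removed.
- **Histogram mode.** Fixed 0.25 MPa bins aligned so bin *centers* sit on
  multiples of the width (a constant field reports its own value);
  ties resolve toward the less negative bin; ≥ 100 valid pixels
  required; NaN (out-of-calibration) pixels are excluded and counted.
- **Statistics.** One-way ANOVA + Tukey HSD via
  `statsmodels.pairwise_tukeyhsd`, with a degenerate zero-variance path
  (flagged, non-significant) and a greedy compact-letter display.
- **Determinism.** All CSV artifacts are written with `%.10g` and a
  units comment line; the pipeline manifest records a config hash, the
  seed and SHA-256 digests, and identical (config, seed) runs are
  byte-identical.
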