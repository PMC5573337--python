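# Methods

This note documents the models, their assumptions, the numerical choices,
and the places where the design was genuinely open.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. Inorganic speciation

The bioassay media are synthetic nutrient solutions (KCl, NaCl, CaCl₂,
MgSO₄, metal chlorides, pH buffered) with no dissolved organic matter, so
the solver covers inorganic equilibria only.

Assumptions:

* **Fixed pH.** The media are buffered; {H⁺} = 10^(−pH) is an input and no
  proton balance is solved.  Buffers are assumed non-complexing and are
  not included in the ionic strength (their contribution at ≤3.6 mM is
  comparable to the neglected charge-balance slack).
* **Open CO₂.** Dissolved CO₂ follows Henry's law at a configurable
  partial pressure, default 10⁻³·⁵ atm.  The carbonate-ligand activities
  are then functions of pH alone:
  {HCO₃⁻} = K_H·Ka₁·pCO₂/{H⁺}, {CO₃²⁻} = Ka₂{HCO₃⁻}/{H⁺}.
  A consequence worth knowing: {HCO₃⁻} and {OH⁻} are both exactly
  proportional to 1/{H⁺}, so any two binding constants attached to an
  M–HCO₃ and an M–OH species are only *jointly* identifiable from data
  that vary pH at fixed pCO₂ (see §3).
* **Davies activity model**, log₁₀γ = −A z²(√I/(1+√I) − 0.3 I), A = 0.51
  at 25 °C, valid to I ≈ 0.5 M; temperature dependence of constants is
  ignored (assays run at 20–25 °C).
* **Species set.** Free ions K⁺, Na⁺, Ca²⁺, Mg²⁺, Cu²⁺, Co²⁺, Cl⁻, SO₄²⁻,
  H⁺/OH⁻, carbonate; complexes CuOH⁺, CuCO₃(aq), CuHCO₃⁺, CoOH⁺,
  CoCO₃(aq), CoHCO₃⁺; ion pairs MgSO₄(aq), CaSO₄(aq), CuSO₄(aq),
  CoSO₄(aq) (off via `include_ion_pairs=False`).  No redox, no solids.

Because pH and pCO₂ fix every ligand activity except sulfate, each metal's
mass balance is linear in its free-ion concentration given free sulfate;
the solver reduces to a Brent root-find on free sulfate nested in the
ionic-strength/activity-coefficient loop (converged at ΔI/I < 10⁻⁹,
tighter than the 10⁻⁶ contract).  Per-metal mass balance is closed-form
and therefore holds to machine precision; the test suite asserts 10⁻⁸
relative.

**Constant database** (`blmtu/data/equilibrium_constants.json`, editable,
provenance per entry).  Carbonate system, hydroxides, CuCO₃ and the
sulfate pairs use standard NIST/Baes–Mesmer-range values.  The M–HCO₃⁺
constants are the one place the literature genuinely disagrees by orders
of magnitude.  Because this module emulates a WHAM-era calculation, the
CuHCO₃⁺ default is the legacy MINTEQ/WHAM-lineage value (log β 14.62 for
Cu²⁺ + H⁺ + CO₃²⁻, i.e. logK 4.29 versus HCO₃⁻); with it the computed
free-Cu²⁺ activity share across the pH 4.5–7.6 media spans ≈78→12 % of
total Cu, and the CuHCO₃⁺/CuCO₃/CuOH⁺ proportions at pH 7.6 match the
reference study's reported WHAM output within ~2 percentage points.  The
CoHCO₃⁺ default is the modern NIST-range value (logK 2.20), which is the
value consistent with the study's *Co EC50 series*; its reported Co
speciation fractions would instead need logK ≈ 3.0.  Those two published
constraints cannot be satisfied by one constant — the package follows the
EC50-consistent choice and the speciation tests document the resulting
~14-point gap at the high-pH Co endpoint.  Users can supply their own
database via `EquilibriumConstantSet.from_json`.

## 2. Dose–response model

All curves are the two-parameter log-logistic with asymptotes fixed at
100 and 0 — exactly the form the occupancy model implies at 50 % effect.
Fitting is nonlinear least squares on the untransformed response
(replicates are *not* averaged by default; `aggregate="mean"` reproduces
the three-replicate averaging of the reference study), with x₅₀
log₁₀-parameterised for positivity and β log-parameterised, a 5×5
deterministic multi-start grid (x₅₀ log-spaced across the data, β from
0.5 to 8), and Levenberg–Marquardt refinement at tolerances 10⁻¹⁴.
Responses are not clipped to [0, 100]: clipping replicate scatter would
bias the asymptotes.  Standard errors are linearised (Jacobian at the
optimum).  Identifiability preconditions: at least four distinct nonzero
exposure levels and responses on both sides of 50 %.

## 3. Single-metal BLM estimation

The loss is on log₁₀EC50{M²⁺} (EC50s span more than a decade; log loss
equalises weight).  H⁺, K⁺, Na⁺ and Ca²⁺ competition are deliberately
excluded — the reference study found their effects negligible for wheat —
leaving Mg²⁺ as the only competing cation.  The occupancy denominator
includes the unoccupied-site "+1" term by default; without it the
predicted EC50 goes to zero as {Mg²⁺} → 0, contradicting the nonzero
intercepts of observed Mg series (`include_unity_term=False` gives the
literal no-unity form).

**Identifiability.**  EC50-level data determine only

* S₀ = (f₅₀/(1−f₅₀)) / K_MBL  (the Mg-intercept scale),
* K_MgBL  (the Mg slope/intercept ratio), and
* k_IM = K_IMBL/K_MBL  (the complex-to-free binding ratios),

because multiplying f₅₀/(1−f₅₀) and every binding constant by a common
factor leaves every EC50 unchanged.  `SingleMetalBLM.fit` therefore
estimates (log S₀, log K_Mg, log k_IM) — a well-posed problem — and
converts to absolute logK using a supplied f₅₀, the convention of the
single-metal BLM literature where f₅₀ is carried over from the
occupancy-scale dose–response.  Leaving `f50=None` profiles the flat
ridge over a 0.1–0.9 grid, warns, and applies a lowest-f₅₀ tie-break; the
fitted EC50s are identical for every grid value, which the tests verify.
A second, subtler degeneracy follows from the open-CO₂ assumption (§1):
K_CuHCO₃BL and K_CuOHBL enter only through the combination
(K_HCO₃·{HCO₃⁻} + K_OH·{OH⁻}) ∝ 1/{H⁺}, so only that combination is
estimable; the reported individual values are a point on the flat line.
Design preconditions: ≥3 Mg levels at one pH (else the Mg axis is
deficient) and ≥3 pH levels at one Mg when complex constants are
requested.

Multi-start: K_Mg starts {10¹, 10²·⁵, 10⁴, 10⁵·⁵}, complex-ratio starts
{10⁻¹, 10¹}, S₀ from the median log EC50; trust-region least squares with
bounds log₁₀S₀ ∈ [−14, 2], logK_Mg ∈ [0, 10], log₁₀k_IM ∈ [−8, 6].
Standard errors by the delta method on the transformed parameters.

## 4. Mixture toxic units and model comparison

In a mixture, each metal's occupied fraction uses its own single-metal
parameter set evaluated on the shared speciated chemistry; the other
metal's occupancy is not added to the denominator by default because the
Cu-only and Co-only fits return *different* Mg constants and no coherent
joint denominator exists (`cross_metal_competition=True` adds it if both
parameter sets are trusted jointly).  TU_f adds f/f₅₀ over metals; TU_M
adds free-ion activities over one global EC50 pair — deliberately
chemistry-blind, since that is the model being tested against.  RMSE and
R² are computed between observed RNE and the fitted pooled curve, in
percentage points.  Interaction calls: additive when the TU50 confidence
interval (or, without one, a configurable ±0.2 band — wide enough to
cover the 0.88–1.15 range that mixture studies typically declare "close
to 1") contains 1; synergistic/antagonistic when entirely below/above.

## 5. Synthetic data

The generator reproduces the reference study design: 12 media (Mg 0.05,
0.5, 1.0, 2.0 mM at pH 6.0; pH 4.5–7.6 at 0.05 mM Mg; 0.08 K / 2.0 Na /
0.2 Ca mM background), seven-level two-fold dose grids (Cu 0.2–12.8 µM,
Co 20–1280 µM, mixtures at Cu:Co = 1:100 molar so the Co grid is implied
by the Cu grid), an undosed control, triplicates, and additive Gaussian
noise on RNE with σ = 5 percentage points — typical scatter for
root-elongation assays.  The exact seven-level grids are an inference
from the stated ranges: 0.2–12.8 µM is exactly two-fold spacing over
seven levels.  All randomness derives from one integer seed through fixed
per-purpose spawn keys, so call order cannot change any stream.

Single-metal truth curves are log-logistic in free-ion activity with the
BLM-predicted per-medium EC50 — the scale on which per-medium fits are
reported, and the choice that makes noise-free round-trips exact.  The
occupancy-scale alternative (`response_scale="site_fraction"`) is
provided but is not exactly log-logistic in {M²⁺} (f saturates at 1; with
f₅₀ = 0.66 its response floor stays above ~10 %), so it is not the
default.  Mixture truth is RNE = 100/(1 + (TU_f/λ)^β); λ = 1 is exact
additivity, and λ ≠ 1 injects interaction that the classifier must
recover.

What the generator does **not** emulate: germination/mortality,
measurement rounding, between-pot random effects, replicate correlation,
and any real deviation of wheat from the BLM itself.  Green recovery
tests therefore demonstrate that the estimators invert the assumed model
at realistic noise — not that the model is true of wheat.

## 6. Known inconsistencies in the published reference values

Carried in `reference_study.published_summaries()` verbatim, flagged, and
never "corrected":

* The Co EC50s at Mg 0.5 mM (51.52 µM) and Mg 1.0 mM (438.34 µM) break
  the monotone, linear-in-{Mg²⁺} pattern the study itself reports
  (R² = 0.97); no rescaling makes all four Mg-series values consistent
  with the published constants.
* The published low-pH Co EC50s (pH 4.5–5.5) rise ~1.9-fold above the
  pH 6 value, while the published Co constant set — no H⁺ competition,
  one CoHCO₃⁺ term that vanishes at low pH — predicts a flat EC50 there.
  One acceptance test asserts the factor-2 agreement anyway and fails by
  design, as an honest record of the discrepancy.
* The reported Co speciation fractions and Co EC50 series imply CoHCO₃⁺
  solution constants an order of magnitude apart (§1).

## 7. Problem sizes

Default study sizes are used throughout: 12 media, 8 dose levels,
triplicates (288 observations per assay type).  Stochastic suites use 200
seeded replicates for the dose–response coverage, constant-recovery and
TU50-coverage checks, reusing the deterministic speciation across
replicates so only noise and refitting vary.
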