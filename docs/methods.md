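# Methods

This note documents the models implemented in `omzsed`, the assumptions
behind them, the defaults of the synthetic-core generator, and the
numerical choices made where the design was genuinely open.

## Diffusive sulfate flux

Pore-water sulfate in organic-rich slope sediments is consumed by
organoclastic sulfate reduction and, near a sulfate–methane transition
zone (SMTZ), by anaerobic oxidation of methane. Under steady state the
depth-integrated (net) sulfate reduction rate equals the diffusive flux
through the sediment, given by Fick's first law:

    J_SO4 = φ · Ds · (dC/dX)

with φ the average sediment porosity (fraction), dC/dX the linear sulfate
concentration gradient (mM cm⁻¹, magnitude of the OLS slope of sulfate
against depth), and Ds the tortuosity-corrected diffusivity

    Ds = Do / [1 + n (1 − φ)]

with n = 3 appropriate for clays and silts. The free-seawater sulfate
diffusivity Do depends on bottom-water temperature; `omzsed` models it as
a configurable linear function Do(T) = a + b·T with literature-derived
defaults a = 4.96 × 10⁻⁶ cm² s⁻¹, b = 2.0 × 10⁻⁷ cm² s⁻¹ °C⁻¹
(tabulated tracer diffusivities at seawater salinity: ≈5.0 × 10⁻⁶ at
0 °C rising to ≈1.0 × 10⁻⁵ at 25 °C). The coefficients live in
`FluxParameters`, are explicitly overridable, and are never hard-coded in
the flux operations. Units: dC/dX in mM cm⁻¹ is converted to
mmol cm⁻⁴ (× 10⁻³) and the second-based diffusivity scaled by
3.1536 × 10⁷ s yr⁻¹, so J comes out in mmol cm⁻² yr⁻¹.

Assumptions and conventions:

- Steady state; no transient or reactive-transport correction.
- The signed OLS slope is retained; its magnitude enters the flux law,
  and a positive (increasing-with-depth) slope is flagged as anomalous.
- The fit window defaults to the whole core; an explicit window can
  exclude the deep, sulfate-depleted section where the profile flattens
  and linearity fails.
- Depths are cm below seafloor, positive downward, sample depth = slab
  midpoint.

## Solid phase, porosity, isotopes

TOC = TC − TIC (wt%); the molar TOC/TN ratio is
(TOC/12.011)/(TN/14.007); porosity is 100 × pore-water volume / wet
sediment volume. The sulfur-isotope offset Δ = δ³⁴S_SO₄ − δ³⁴S_HS is
computed per depth where both members of the pair exist (sulfide is
often below detection) and summarized as mean ± sd per core.

## SMTZ detection

The SMTZ is reported as the bracketing pair of consecutive sampled
depths at the first depth where sulfate has fallen below a floor
(default 1 mM) while methane exceeds a rise factor (default 10) times
its shallow-depth median (the median over the top quarter of the cored
interval, at least three samples). Both thresholds are configurable;
neither is a measured constant, and the defaults were chosen so that a
core whose sulfate reaches the floor at ~260 cmbsf with a coincident
methane rise is bracketed by its neighboring samples. If methane was not
measured, the result is marked not-applicable with a reason rather than
silently absent.

## SRB enumeration

Sulfate-reducer richness is the count of OTUs whose taxonomic lineage
belongs to taxa known to reduce sulfate dissimilatorily: 15 genera
(Desulfacinum, Desulfobacca, Desulfobaculum, Desulfocurvus,
Desulfoglaeba, Desulfomonas, Desulfomonile, Desulforhabdus, Desulfosoma,
Desulfovibrio, Desulfovirga, Desulfurella, Desulfuromonas,
Desulfuromusa, Thermodesulforhabdus) plus six deltaproteobacterial
families counted in their entirety (Desulfarculaceae,
Desulfobacteraceae, Desulfobulbaceae, Desulfohalobiaceae,
Desulfomicrobiaceae, Desulfonatronaceae). Matching is case-insensitive
and **by exact rank name**: the genus list governs only the genus rank
and the family list only the family rank, which prevents
substring-style double matching (e.g. Desulfovibrio vs the family
Desulfovibrionaceae, which is *not* on the family list). Archaeal
lineages are always excluded — the enumeration applies to bacterial 16S
surveys, so archaeal sulfate reducers (Archaeoglobus,
Desulfurococcus-like Crenarchaeota) are out of scope.

Single-read OTUs are removed before enumeration. The ordering is
enforced by contract: `srb_otu_count` refuses a table whose
`singletons_removed` flag is unset. Per-core depth profiles are
max-normalized: `normalized_i = count_i / max_j(count_j)`, undefined
(an error) when a core has no SRB OTU at any depth.

Richness statistics: the rarefaction expectation is the exact
hypergeometric form E[S] = Σᵢ [1 − C(N−Nᵢ, m)/C(N, m)] evaluated with
log-gamma binomials; ACE uses the standard abundance-based coverage
form with rare threshold 10 (the usual convention), the rare-class CV
floored at zero, and a Chao1 fallback when every rare read is a
singleton (coverage zero makes ACE undefined).

## Three-zone density model

Down-core profiles of max-normalized SRB-OTU counts follow a recurring
three-zone structure — shallow exponential decay, middle Gaussian, deep
exponential rise:

    decay:    y = y₀ + A₁ e^(−x/t₁)
    gaussian: y = y₀ + A/(w√(π/2)) e^(−2(x−x_c)²/w²)
    growth:   y = y₀ + A₁ e^(x/t₁)

A baseline offset y₀ is always fitted (the fitted forms used in practice
include it even where the bare densities do not). The objective is the
unweighted residual sum of squares ("χ²" in the curve-fitting sense; the
weighting used by interactive fitting software is not identifiable, so
unweighted least squares is the documented choice), with the reduced
form χ²/(n−p) also reported. Minimization is Levenberg–Marquardt,
capped at 4000 function evaluations, stopping when the relative change
of the reduced χ² falls below 10⁻⁹.

Numerical choices:

- t₁ and w are carried in log space (positivity without bound
  constraints, which plain LM does not support); exponential amplitudes
  are re-anchored at the shallow (decay) or deep (growth) end of the
  fitted window so the Jacobian stays well conditioned even when
  A₁ e^(x/t₁) spans many orders of magnitude. Reported parameters are
  translated back to the absolute-depth forms above.
- Data-driven initialization: y₀ from the minimum, amplitude from the
  data range, t₁ from a third of the window span, Gaussian center at the
  observed peak and width from the half-maximum crossing. Constant data
  yields a degenerate zero-amplitude start with a warning.
- A non-finite objective yields a non-converged `ZoneFit`, not an
  exception.
- Fits are deterministic: same data and start ⇒ bit-identical result.

### Segmentation

`fixed_ranges` mode fits each density on an analyst-supplied depth range
(ranges may overlap, as analyst-chosen zones often do; the growth zone
may be absent). `auto` mode is a reproducible surrogate for segmentation
by inspection: it grid-searches zone boundaries on the sampling grid
(adjacent zones share the boundary sample), minimizing total χ² within
each zone-count class, and accepts the Gaussian and growth zones
sequentially by an extra-sum-of-squares F-test at α = 0.05 in which each
moved boundary counts as one parameter. The F-test replaced a plain BIC
comparison during development because BIC systematically over-selected
extra zones on single-zone profiles (the boundary search inflates the
effective degrees of freedom); on seeded experiments the F-test
separates one-zone from three-zone truths cleanly. Profiles without a
genuine peak or deep rise therefore report those zones absent.

## Synthetic-core generator

The generator emulates an eight-station transect of ~3 m gravity cores
across an oxygen-minimum-zone water-depth gradient (225–1275 mbsl),
sampled every 15 cm at slab midpoints. Station defaults span the field
extremes: sulfate gradients 0.015–0.11 mM cm⁻¹, porosities 0.55–0.78,
bottom-water temperatures 5.5–15 °C, oxygen 2.5–40 µM, with the two
OMZ-center stations carrying an SMTZ at 250–260 cmbsf and the edge
stations none. Closed-form models:

- sulfate: max(0, C_top − g·x), C_top = 28 mM;
- δ³⁴S_SO₄: Rayleigh distillation δ(x) = δ_top + ε·ln(C_top/C(x)) with
  ε = 10‰ and the residual fraction floored at 10% (keeps the log
  bounded through near-complete drawdown); δ³⁴S_HS = δ³⁴S_SO₄ − Δ with
  Δ = 46.7‰;
- methane: logistic rise across the SMTZ; sulfide: Gaussian peak at the
  SMTZ (up to ~2000 µM); DIC and NH₄⁺ increase linearly; δ¹³C_DIC is
  depleted down-core (strongly for SMTZ-bearing cores);
- solid phase: TOC declining linearly down-core, TN = TOC at a molar
  C/N of 13.6, constant TIC;
- SRB counts: Poisson around peak_count × (three-zone intensity), with
  peak_count = 30 — counts are small non-negative integers, so Poisson
  is the simplest defensible count model. The canonical zone truth is a
  decay (y₀ = 0.05, A₁ = 0.9, t₁ = 40 cm) over 0–90 cm, a Gaussian
  (w = 60 cm, x_c = 145 cm) over 90–200 cm, and a growth zone mirroring
  the decay over 200–300 cm; one edge station omits the growth zone.
- taxonomy tables: zone-driven SRB OTUs carry ≥ 2 reads and lineages
  drawn uniformly from the SRB taxon pools; a disjoint non-SRB pool
  (including the sulfur-oxidizers Arcobacter, Paracoccus, Sulfurimonas,
  Thiohalomonas, Thiohalophilus) provides negatives; an extra 20% of
  single-read OTUs is sprinkled on top for the singleton filter to
  remove, so the generator's truth count equals the post-filter SRB
  count by construction.

Noise is additive Gaussian per analyte, truncated at physical bounds
(field reproducibilities are symmetric, e.g. ±0.2 ppm for sulfate,
±0.3‰ for δ³⁴S); defaults: sulfate 0.3 mM, sulfide 20 µM, DIC 0.1 mM,
NH₄⁺ 10 µM, isotopes 0.3/0.1‰. Noise is independent across depths — no
within-core autocorrelation is modeled, which is a simplification;
real profiles have correlated structure from diagenesis and coring
disturbance. The generator also makes no attempt at sequencing-level
realism (no reads, chimeras, or PCR bias), so passing tests demonstrate
estimator correctness under the stated generative model, not robustness
to upstream sequencing artifacts.

All randomness flows from a single integer seed; fixed seed ⇒
bit-identical output. Per-station seeds in a transect derive from
`(master_seed × 1000003 + CRC32(station_id)) mod 2³¹`, so adding or
removing a station never perturbs the others.

## Problem sizes

The test suite and `scripts/acceptance.py` use desk-scale experiment
sizes chosen to make sampling error small relative to the tolerances
they check: 1000 random tuples for the flux-chain identity, 100 seeded
replicates for gradient and zone-parameter recovery, 50 for boundary
recovery, 25–60 for robustness checks, cores of 12–20 depths. Truth
boundaries (90/200 cm) intentionally fall off the midpoint sampling
grid, so the best achievable boundary error is half a grid offset
(2.5–7.5 cm), comfortably inside one sampling interval.

## Known limitations

- The Do(T) default is a linear fit to tabulated diffusivities; outside
  0–30 °C it extrapolates and the code warns or errors.
- The unweighted χ² convention means fitted χ² magnitudes are not
  comparable to values produced by software using statistical weighting
  or histogram binning.
- Zone fits on fewer than p+1 points are refused rather than
  regularized.
- ACE on communities where every rare OTU is a singleton silently (with
  a log notice) becomes Chao1.
- The SMTZ bracket is only as fine as the sampling interval; no
  sub-sample interpolation is attempted.
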