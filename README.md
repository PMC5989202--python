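# omzsed

Coupled carbon–sulfur geochemistry and sulfate-reducer diversity analysis
for sediment cores beneath oxygen minimum zones (OMZs).

Sediments under OMZ waters receive large fluxes of labile organic matter
and host intense microbial sulfate reduction. Interpreting such a system
requires joining two kinds of data per coring station: depth-indexed
pore-water/solid-phase chemistry (sulfate, sulfide, methane, DIC, NH₄⁺,
δ³⁴S, δ¹³C, TC/TIC/TN) and 16S-derived OTU taxonomy tables. `omzsed`
provides a tested pipeline for the standard reductions of both:

- **Diffusive sulfate flux** from Fick's first law at steady state,
  `J_SO4 = φ·Ds·(dC/dX)`, with the tortuosity correction
  `Ds = Do/[1 + n(1−φ)]` (n = 3 for clays and silts) and a configurable
  linear `Do(T)` for free-seawater sulfate diffusivity. Gradients come
  from OLS fits of sulfate (mM) against depth (cm), optionally windowed
  to the linear section.
- **Sulfate–methane transition zone (SMTZ)** placement as the bracketing
  pair of sampled depths where sulfate drops below a floor while methane
  rises above a multiple of its shallow baseline.
- **Sulfur-isotope offsets** Δ = δ³⁴S_SO₄ − δ³⁴S_HS per depth with
  per-core summaries; TOC = TC − TIC, molar TOC/TN, porosity.
- **Sulfate-reducing bacteria (SRB) enumeration** from RDP-style
  taxonomy tables: a 15-genus + 6-family dissimilatory-sulfate-reducer
  filter (bacteria only, exact rank-name matching), singleton removal
  enforced before counting, per-core max-normalized depth profiles, and
  rarefaction/ACE richness statistics.
- **Three-zone density model** of SRB diversity versus depth: an upper
  exponential decay `y₀ + A₁e^(−x/t₁)`, a middle Gaussian
  `y₀ + A/(w√(π/2))·e^(−2(x−x_c)²/w²)`, and a lower exponential rise,
  fitted by Levenberg–Marquardt χ² minimization (≤ 4000 iterations,
  reduced-χ² tolerance 10⁻⁹), with either analyst-fixed zone ranges or
  automatic boundary search.
- **Synthetic transect generator** producing eight-station,
  ~3-m-core datasets with known ground truth (linear sulfate drawdown,
  Rayleigh ³⁴S enrichment, SMTZ anomalies, Poisson SRB counts over the
  three-zone structure), so every estimator is testable end to end
  without field data.

See `docs/methods.md` for model details, defaults, and limitations.

## Worked example

```python
from omzsed import synthetic, geochem, srb, zones

spec = synthetic.default_transect_specs(master_seed=1)[5]   # OMZ-center station
core = synthetic.generate_core(spec)

params = geochem.FluxParameters(porosity=spec.porosity,
                                bottom_water_temp=spec.bottom_water_temp)
flux = geochem.compute_flux(core.porewater, params,
                            window=(0, 0.95 * 28 / spec.sulfate_gradient))
smtz = geochem.detect_smtz(core.porewater)
profile = srb.build_srb_profile(core.taxonomy)
seg = zones.segment_and_fit(profile, mode="auto")
```

printing the pieces gives:

```
station          : SSK42/6 (530 mbsl)
dC/dX            : 0.1017 mM/cm
Do, Ds           : 7.160e-06, 4.091e-06 cm^2/s
J_SO4            : 0.0098 mmol cm^-2 yr^-1
SMTZ bracket     : 247.5-262.5 cmbsf
SRB-OTU max      : 35 (at 142.5 cmbsf)
zone decay    : D = 7.5-97.5 cm, chi2 = 0.039
zone gaussian : D = 97.5-202.5 cm, chi2 = 0.014
zone growth   : D = 202.5-292.5 cm, chi2 = 0.033
```

The recovered gradient (0.1017 mM cm⁻¹) matches this station's
generating truth (0.1038) to within the noise; the flux lands at the
high end of the transect envelope, as expected for an OMZ-center core;
the SMTZ bracket spans the generating 260 cmbsf crossing; and the
automatic segmentation recovers the three generating zones with
boundaries within one sampling interval of the truth (90 and 200 cm).

The same chain is scriptable from a shell:

```sh
omzsed simulate --seed 1 --out sim/
omzsed flux --core sim/SSK42_6_porewater.csv --meta station.yaml
omzsed smtz --core sim/SSK42_6_porewater.csv
omzsed srb --manifest sim/SSK42_6_taxonomy/manifest.csv --out srb.csv
omzsed fit-zones --profile srb.csv
omzsed report --seed 1 --out report/
```

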