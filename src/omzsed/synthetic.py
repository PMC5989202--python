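"""Synthetic OMZ sediment cores with known ground truth.

Generates transects of gravity-core-like datasets (pore-water chemistry,
solid-phase carbon/nitrogen, and per-depth OTU taxonomy tables) that
emulate the structure of upper-continental-slope cores beneath an oxygen
minimum zone: linear sulfate drawdown with station-specific gradients,
sulfide and methane anomalies around a sulfate-methane transition zone
(SMTZ) for the stations that have one, down-core 34S enrichment of the
sulfate pool by Rayleigh distillation, monotone DIC/ammonium build-up,
and sulfate-reducer OTU counts following the three-zone
decay/Gaussian/growth depth structure.

Every generated quantity derives from a closed-form model plus additive,
truncated Gaussian noise, so downstream estimators can be tested against
the exact generating parameters.  All randomness flows from a single
integer seed; a fixed seed reproduces a core bit-identically, and
per-core seeds in a transect are derived from the master seed and the
station id alone, so adding a station never perturbs the others.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .geochem import CoreProfile, SolidPhaseProfile, ValidationError
from .srb import Lineage, OtuRecord, TaxonomyTable
from .zones import ZoneKind, ZoneParameters, zone_density

# default per-analyte noise standard deviations (same units as the analyte)
DEFAULT_NOISE_SD: Dict[str, float] = {
    "sulfate": 0.3,    # mM
    "sulfide": 20.0,   # uM
    "dic": 0.1,        # mM
    "nh4": 10.0,       # uM
    "ch4": 0.005,
    "d34s": 0.3,       # permil
    "d13c": 0.1,       # permil
    "tc": 0.05,        # wt%
    "tn": 0.01,        # wt%
}

# wt% TOC/TN corresponding to a molar ratio of 13.6 (marine organic matter)
_TOC_TN_WT = 13.6 * 12.011 / 14.007


@dataclass(frozen=True)
class ZoneTruth:
    """One generating zone: density kind, parameters, and depth range (cm)."""

    kind: ZoneKind
    params: ZoneParameters
    depth_range: Tuple[float, float]


def default_zone_truth(core_length: float = 300.0,
                       include_growth: bool = True) -> List[ZoneTruth]:
    """Canonical three-zone truth: shallow decay, mid Gaussian, deep growth."""
    b1, b2 = 0.3 * core_length, 2.0 / 3.0 * core_length
    zones = [
        ZoneTruth(ZoneKind.DECAY,
                  ZoneParameters(y0=0.05, a1=0.9, t1=40.0), (0.0, b1)),
        ZoneTruth(ZoneKind.GAUSSIAN,
                  ZoneParameters(y0=0.05, a=0.85 * 60.0 * math.sqrt(math.pi / 2),
                                 w=60.0, xc=(b1 + b2) / 2.0), (b1, b2)),
    ]
    if include_growth:
        zones.append(ZoneTruth(
            ZoneKind.GROWTH,
            ZoneParameters(y0=0.05, a1=0.9 * math.exp(-core_length / 40.0),
                           t1=40.0), (b2, core_length)))
    return zones


@dataclass
class SyntheticCoreSpec:
    """Generating parameters for one synthetic coring station."""

    station_id: str
    water_depth: float              # mbsl
    bottom_water_temp: float        # degC
    bottom_water_o2: float          # uM
    sulfate_gradient: float         # mM cm^-1
    porosity: float                 # fraction
    core_length: float = 300.0      # cm
    sampling_interval: float = 15.0  # cm
    sulfate_top: float = 28.0       # mM
    smtz_depth: Optional[float] = None  # cmbsf
    epsilon_34s: float = 10.0       # permil, Rayleigh enrichment factor
    d34s_so4_top: float = 25.0      # permil VCDT
    delta_so4_hs: float = 46.7      # permil, sulfate-sulfide offset truth
    d13c_toc: float = -20.6         # permil VPDB
    toc_top: float = 3.0            # wt%
    toc_bottom: float = 1.0         # wt%
    tic: float = 1.0                # wt%
    zone_truth: List[ZoneTruth] = field(default_factory=default_zone_truth)
    peak_srb_count: float = 30.0    # expected SRB OTUs at the zone maximum
    n_nonsrb_otus: int = 40
    singleton_fraction: float = 0.2
    mean_reads_per_otu: float = 20.0
    noise_sd: Dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.sampling_interval <= 0:
            raise ValidationError("sampling_interval must be positive")
        if not 0.0 <= self.porosity <= 1.0:
            raise ValidationError("porosity outside [0, 1]")
        if self.sulfate_top <= 0:
            raise ValidationError("sulfate_top must be positive")
        if self.sulfate_gradient < 0:
            raise ValidationError("sulfate_gradient must be >= 0")
        if self.smtz_depth is not None and self.smtz_depth > self.core_length:
            raise ValidationError("smtz_depth beyond core length")
        merged = dict(DEFAULT_NOISE_SD)
        merged.update(self.noise_sd)
        if any(v < 0 for v in merged.values()):
            raise ValidationError("noise_sd values must be >= 0")
        self.noise_sd = merged

    def depths(self) -> np.ndarray:
        """Sampled depths: slab midpoints on the sampling grid (cmbsf)."""
        half = self.sampling_interval / 2.0
        return np.arange(half, self.core_length + 1e-9, self.sampling_interval)


@dataclass
class SyntheticCore:
    """A fully generated station: data tables plus the generating truth."""

    spec: SyntheticCoreSpec
    porewater: CoreProfile
    solidphase: SolidPhaseProfile
    taxonomy: List[TaxonomyTable]
    truth: Dict


# ---------------------------------------------------------------------------
# closed-form models (noise-free)
# ---------------------------------------------------------------------------

def sulfate_model(spec: SyntheticCoreSpec, x: np.ndarray) -> np.ndarray:
    return np.maximum(0.0, spec.sulfate_top - spec.sulfate_gradient * x)


def d34s_so4_model(spec: SyntheticCoreSpec, x: np.ndarray) -> np.ndarray:
    """Rayleigh enrichment: delta(x) = delta_top + eps * ln(C_top / C(x)).

    The residual sulfate fraction is floored at 10% so the log stays
    bounded where drawdown is nearly complete.
    """
    frac = np.maximum(sulfate_model(spec, x) / spec.sulfate_top, 0.1)
    return spec.d34s_so4_top + spec.epsilon_34s * np.log(1.0 / frac)


def ch4_model(spec: SyntheticCoreSpec, x: np.ndarray,
              background: float = 0.002, ch4_max: float = 1.5,
              rise_width: float = 7.5) -> np.ndarray:
    if spec.smtz_depth is None:
        return np.full_like(x, background)
    return background + ch4_max / (1.0 + np.exp(-(x - spec.smtz_depth)
                                                / rise_width))


def sulfide_model(spec: SyntheticCoreSpec, x: np.ndarray,
                  peak: float = 2000.0, width: float = 60.0) -> np.ndarray:
    if spec.smtz_depth is None:
        # no SMTZ within the cored interval: mild OSR-driven build-up
        return 50.0 * x / spec.core_length
    return peak * np.exp(-0.5 * ((x - spec.smtz_depth) / width) ** 2)


def zone_intensity(zone_truth: Sequence[ZoneTruth], x: np.ndarray) -> np.ndarray:
    """Piecewise normalized SRB intensity at depths x (first matching zone)."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    for i, xi in enumerate(x):
        zone = None
        for zt in zone_truth:
            lo, hi = zt.depth_range
            if lo <= xi <= hi:
                zone = zt
                break
        if zone is None:
            # outside every range: nearest zone by range midpoint
            zone = min(zone_truth,
                       key=lambda zt: abs(xi - sum(zt.depth_range) / 2.0))
        out[i] = zone_density(zone.kind, zone.params, xi)
    if np.any(out < 0):
        raise ValidationError("zone intensity negative at a sampled depth")
    return out


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _noisy(rng: np.random.Generator, model: np.ndarray, sd: float,
           floor: Optional[float] = 0.0) -> np.ndarray:
    if sd > 0:
        model = model + rng.normal(0.0, sd, size=model.shape)
    if floor is not None:
        model = np.maximum(model, floor)
    return model


def generate_porewater(spec: SyntheticCoreSpec,
                       rng: Optional[np.random.Generator] = None) -> CoreProfile:
    """Pore-water chemistry for one station from the closed-form models."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    x = spec.depths()
    sd = spec.noise_sd
    so4 = _noisy(rng, sulfate_model(spec, x), sd["sulfate"])
    hs = _noisy(rng, sulfide_model(spec, x), sd["sulfide"])
    dic = _noisy(rng, 2.5 + 0.035 * x, sd["dic"])
    nh4 = _noisy(rng, 60.0 + 6.0 * x, sd["nh4"])
    ch4 = _noisy(rng, ch4_model(spec, x), sd["ch4"])
    d34s_so4 = _noisy(rng, d34s_so4_model(spec, x), sd["d34s"], floor=None)
    d34s_hs = _noisy(rng, d34s_so4_model(spec, x) - spec.delta_so4_hs,
                     sd["d34s"], floor=None)
    depletion = 30.0 if spec.smtz_depth is not None else 8.0
    d13c_dic = _noisy(rng, -2.0 - depletion * x / spec.core_length,
                      sd["d13c"], floor=None)
    d13c_toc = _noisy(rng, np.full_like(x, spec.d13c_toc), sd["d13c"],
                      floor=None)
    return CoreProfile(
        station_id=spec.station_id, depth=x, sulfate=so4, sulfide=hs,
        dic=dic, nh4=nh4, ch4=ch4, d34s_so4=d34s_so4, d34s_hs=d34s_hs,
        d13c_dic=d13c_dic, d13c_toc=d13c_toc,
    )


def generate_solidphase(spec: SyntheticCoreSpec,
                        rng: Optional[np.random.Generator] = None
                        ) -> SolidPhaseProfile:
    """Solid-phase TC/TIC/TN with linearly declining organic carbon."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 1)
    x = spec.depths()
    toc = spec.toc_top + (spec.toc_bottom - spec.toc_top) * x / spec.core_length
    toc = _noisy(rng, toc, spec.noise_sd["tc"])
    tn = _noisy(rng, toc / _TOC_TN_WT, spec.noise_sd["tn"], floor=1e-4)
    tic = np.full_like(x, spec.tic)
    return SolidPhaseProfile(station_id=spec.station_id, depth=x,
                             tc=tic + toc, tic=tic, tn=tn)


# Lineage pools.  Orders/families for the genus-listed SRB need only be
# plausible; classification is by the genus (or family) rank itself.
_SRB_GENUS_LINEAGES = [
    f"Bacteria;Proteobacteria;Deltaproteobacteria;Desulfovibrionales;"
    f"Desulfovibrionaceae;{g}"
    for g in ("Desulfovibrio", "Desulfomonas")
] + [
    f"Bacteria;Proteobacteria;Deltaproteobacteria;Desulfobacterales;"
    f"unclassified;{g}"
    for g in ("Desulfacinum", "Desulfobacca", "Desulfobaculum",
              "Desulfocurvus", "Desulfoglaeba", "Desulfomonile",
              "Desulforhabdus", "Desulfosoma", "Desulfovirga",
              "Desulfurella", "Desulfuromonas", "Desulfuromusa",
              "Thermodesulforhabdus")
]
_SRB_FAMILY_LINEAGES = [
    f"Bacteria;Proteobacteria;Deltaproteobacteria;Desulfobacterales;{f};"
    f"unclassified"
    for f in ("Desulfarculaceae", "Desulfobacteraceae", "Desulfobulbaceae",
              "Desulfohalobiaceae", "Desulfomicrobiaceae",
              "Desulfonatronaceae")
]
SRB_LINEAGE_POOL = _SRB_GENUS_LINEAGES + _SRB_FAMILY_LINEAGES

NONSRB_LINEAGE_POOL = [
    "Bacteria;Proteobacteria;Epsilonproteobacteria;Campylobacterales;"
    "Campylobacteraceae;Arcobacter",
    "Bacteria;Proteobacteria;Alphaproteobacteria;Rhodobacterales;"
    "Rhodobacteraceae;Paracoccus",
    "Bacteria;Proteobacteria;Epsilonproteobacteria;Campylobacterales;"
    "Helicobacteraceae;Sulfurimonas",
    "Bacteria;Proteobacteria;Gammaproteobacteria;Chromatiales;"
    "Ectothiorhodospiraceae;Thiohalomonas",
    "Bacteria;Proteobacteria;Gammaproteobacteria;Chromatiales;"
    "Ectothiorhodospiraceae;Thiohalophilus",
    "Bacteria;Firmicutes;Bacilli;Bacillales;Bacillaceae;Bacillus",
    "Bacteria;Proteobacteria;Gammaproteobacteria;Pseudomonadales;"
    "Pseudomonadaceae;Pseudomonas",
    "Bacteria;Chloroflexi;Anaerolineae;Anaerolineales;Anaerolineaceae;"
    "Anaerolinea",
    "Bacteria;Bacteroidetes;Flavobacteriia;Flavobacteriales;"
    "Flavobacteriaceae;Gramella",
    "Bacteria;Planctomycetes;Planctomycetia;Planctomycetales;"
    "Planctomycetaceae;Planctomyces",
]


def generate_taxonomy(spec: SyntheticCoreSpec,
                      rng: Optional[np.random.Generator] = None,
                      ) -> Tuple[List[TaxonomyTable], np.ndarray]:
    """Per-depth OTU taxonomy tables plus the true SRB-OTU counts.

    SRB-OTU counts are drawn Poisson around the scaled three-zone
    intensity.  The truth count refers to non-singleton SRB OTUs: the
    zone-driven OTUs all carry >= 2 reads, while an extra
    ``singleton_fraction`` of single-read OTUs (from both lineage pools)
    is sprinkled on top, to be discarded by the singleton filter.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 2)
    x = spec.depths()
    lam = spec.peak_srb_count * zone_intensity(spec.zone_truth, x)
    tables: List[TaxonomyTable] = []
    truth_counts = np.zeros(x.size, dtype=int)
    for i, xi in enumerate(x):
        n_srb = int(rng.poisson(lam[i]))
        truth_counts[i] = n_srb
        records: List[OtuRecord] = []
        for k in range(n_srb):
            lin = SRB_LINEAGE_POOL[int(rng.integers(len(SRB_LINEAGE_POOL)))]
            reads = 2 + int(rng.poisson(spec.mean_reads_per_otu))
            records.append(OtuRecord(f"OTU{i:03d}_S{k:04d}",
                                     Lineage.from_string(lin), reads))
        for k in range(spec.n_nonsrb_otus):
            lin = NONSRB_LINEAGE_POOL[int(rng.integers(len(NONSRB_LINEAGE_POOL)))]
            reads = 2 + int(rng.poisson(spec.mean_reads_per_otu))
            records.append(OtuRecord(f"OTU{i:03d}_N{k:04d}",
                                     Lineage.from_string(lin), reads))
        n_single = int(spec.singleton_fraction * len(records))
        pool = SRB_LINEAGE_POOL + NONSRB_LINEAGE_POOL
        for k in range(n_single):
            lin = pool[int(rng.integers(len(pool)))]
            records.append(OtuRecord(f"OTU{i:03d}_X{k:04d}",
                                     Lineage.from_string(lin), 1))
        tables.append(TaxonomyTable(station_id=spec.station_id,
                                    depth=float(xi), records=records))
    return tables, truth_counts


def generate_core(spec: SyntheticCoreSpec) -> SyntheticCore:
    """Generate every table for one station from its single seed."""
    porewater = generate_porewater(spec)
    solid = generate_solidphase(spec)
    taxonomy, truth_counts = generate_taxonomy(spec)
    truth = {
        "station_id": spec.station_id,
        "sulfate_top": spec.sulfate_top,
        "sulfate_gradient": spec.sulfate_gradient,
        "porosity": spec.porosity,
        "bottom_water_temp": spec.bottom_water_temp,
        "smtz_depth": spec.smtz_depth,
        "epsilon_34s": spec.epsilon_34s,
        "delta_so4_hs": spec.delta_so4_hs,
        "peak_srb_count": spec.peak_srb_count,
        "zone_truth": [
            {"kind": zt.kind.value, "depth_range": list(zt.depth_range),
             "params": {k: v for k, v in vars(zt.params).items()
                        if v is not None}}
            for zt in spec.zone_truth
        ],
        "srb_counts": truth_counts.tolist(),
        "seed": spec.seed,
    }
    return SyntheticCore(spec=spec, porewater=porewater, solidphase=solid,
                         taxonomy=taxonomy, truth=truth)


def derive_core_seed(master_seed: int, station_id: str) -> int:
    """Deterministic per-station seed: CRC32 of the id folded into the master.

    Depends only on (master_seed, station_id), so adding or removing other
    stations never changes a core.  Kept below 2**31.
    """
    return (master_seed * 1000003 + zlib.crc32(station_id.encode("utf-8"))) \
        % (2 ** 31)


def generate_transect(specs: Sequence[SyntheticCoreSpec],
                      master_seed: Optional[int] = None) -> List[SyntheticCore]:
    """Generate independent cores; seeds derived per station when a master
    seed is given."""
    ids = [s.station_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate station ids in transect")
    cores = []
    for spec in specs:
        if master_seed is not None:
            spec = replace_seed(spec, derive_core_seed(master_seed,
                                                       spec.station_id))
        cores.append(generate_core(spec))
    return cores


def replace_seed(spec: SyntheticCoreSpec, seed: int) -> SyntheticCoreSpec:
    from dataclasses import replace
    return replace(spec, seed=seed, noise_sd=dict(spec.noise_sd))


def default_transect_specs(master_seed: int = 0) -> List[SyntheticCoreSpec]:
    """Eight stations spanning 225-1275 mbsl across an OMZ water-depth
    transect.

    Gradients span the printed field extremes (0.015 mM/cm at the shallow
    OMZ edge to 0.11 mM/cm at the OMZ center); the two center stations
    carry an SMTZ in the 250-275 cmbsf window; organic carbon and SRB
    zone amplitudes peak mid-transect.
    """
    rows = [
        # id, mbsl, T degC, O2 uM, grad, phi, smtz, toc_top, growth?
        ("SSK42/1", 1275.0, 5.5, 40.0, 0.025, 0.66, None, 1.5, False),
        ("SSK42/2", 1100.0, 6.5, 25.0, 0.035, 0.68, None, 2.0, True),
        ("SSK42/3", 950.0, 7.5, 15.0, 0.060, 0.70, None, 2.5, True),
        ("SSK42/4", 750.0, 9.0, 8.0, 0.075, 0.74, None, 3.0, True),
        ("SSK42/5", 580.0, 10.5, 3.0, 0.090, 0.78, None, 5.0, True),
        ("SSK42/6", 530.0, 11.0, 2.5, 27.0 / 260.0, 0.75, 260.0, 4.5, True),
        ("SSK42/7", 470.0, 11.5, 4.0, 0.110, 0.72, 250.0, 4.0, True),
        ("SSK42/8", 225.0, 15.0, 15.0, 0.015, 0.55, None, 1.2, False),
    ]
    specs = []
    for sid, wd, t, o2, grad, phi, smtz, toc, growth in rows:
        specs.append(SyntheticCoreSpec(
            station_id=sid, water_depth=wd, bottom_water_temp=t,
            bottom_water_o2=o2, sulfate_gradient=grad, porosity=phi,
            smtz_depth=smtz, toc_top=toc, toc_bottom=max(0.4, toc / 3.0),
            zone_truth=default_zone_truth(include_growth=growth),
            seed=derive_core_seed(master_seed, sid),
        ))
    return specs


def zone_profile_series(zone_truth: Sequence[ZoneTruth],
                        depths: np.ndarray,
                        noise_sd: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Noisy normalized-count series straight from the zone densities.

    Convenience for fitting experiments that bypass the Poisson/taxonomy
    layer: intensity plus truncated Gaussian noise.
    """
    y = zone_intensity(zone_truth, np.asarray(depths, dtype=float))
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return np.maximum(y, 0.0)
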