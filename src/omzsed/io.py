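"""Table readers/writers, configuration, and per-transect report assembly.

All tables are plain UTF-8 CSV/TSV with "." decimals and empty cells for
missing values; units are fixed by the column schema (cm, mM, uM, wt%,
permil) and never auto-detected.  One file per core per table kind.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import geochem, srb, zones
from .geochem import (CoreProfile, FluxParameters, SolidPhaseProfile,
                      ValidationError)
from .srb import Lineage, OtuRecord, SrbDepthProfile, TaxonomyTable

log = logging.getLogger(__name__)

# CSV column -> CoreProfile field
CORE_COLUMNS = {
    "depth_cmbsf": "depth",
    "so4_mM": "sulfate",
    "hs_uM": "sulfide",
    "dic_mM": "dic",
    "nh4_uM": "nh4",
    "ch4": "ch4",
    "d34s_so4": "d34s_so4",
    "d34s_hs": "d34s_hs",
    "d13c_dic": "d13c_dic",
    "d13c_toc": "d13c_toc",
}
CORE_MANDATORY = ("depth_cmbsf", "so4_mM")

SOLID_COLUMNS = ("depth_cmbsf", "tc_wt", "tic_wt", "tn_wt")


class SchemaError(ValidationError):
    """Raised when an input file does not match its declared schema."""


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class StationMeta:
    station_id: str
    porosity: float
    bottom_water_temp: float
    bottom_water_o2: float = float("nan")
    water_depth: float = float("nan")

    def flux_parameters(self, **overrides) -> FluxParameters:
        return FluxParameters(porosity=self.porosity,
                              bottom_water_temp=self.bottom_water_temp,
                              **overrides)


@dataclass
class RunConfig:
    """Everything a pipeline run needs beyond the data tables themselves."""

    stations: Dict[str, StationMeta] = field(default_factory=dict)
    do_intercept: float = geochem.DEFAULT_DO_INTERCEPT
    do_slope: float = geochem.DEFAULT_DO_SLOPE
    tortuosity_exponent: float = 3.0
    sulfate_floor: float = 1.0          # mM, SMTZ criterion
    methane_rise_factor: float = 10.0   # SMTZ criterion
    zone_mode: str = "auto"
    zone_max_iterations: int = zones.MAX_ITERATIONS
    zone_tolerance: float = zones.REDUCED_CHI2_TOL
    ace_rare_threshold: int = 10
    seed: int = 0

    def flux_parameters(self, station_id: str) -> FluxParameters:
        meta = self.stations[station_id]
        return FluxParameters(
            porosity=meta.porosity,
            bottom_water_temp=meta.bottom_water_temp,
            tortuosity_exponent=self.tortuosity_exponent,
            do_intercept=self.do_intercept,
            do_slope=self.do_slope,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["stations"] = {k: StationMeta(**v)
                         for k, v in d.get("stations", {}).items()}
        return cls(**d)


def write_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def read_config(path) -> RunConfig:
    return RunConfig.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# core / solid-phase profiles
# ---------------------------------------------------------------------------

def write_core_profile(profile: CoreProfile, path) -> None:
    data = {"depth_cmbsf": profile.depth}
    for col, attr in CORE_COLUMNS.items():
        if col == "depth_cmbsf":
            continue
        arr = getattr(profile, attr)
        if arr is not None:
            data[col] = arr
    pd.DataFrame(data).to_csv(path, index=False)


def read_core_profile(path, station_id: Optional[str] = None) -> CoreProfile:
    """Read a per-core pore-water CSV, validating schema and monotone depth.

    Malformed (non-numeric) cells are reported with their line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    for col in CORE_MANDATORY:
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing mandatory column {col!r}")
    numeric = {}
    for col in df.columns:
        if col not in CORE_COLUMNS:
            log.warning("%s: ignoring unknown column %r", path.name, col)
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & vals.isna()
        if bad.any():
            lines = [i + 2 for i in df.index[bad]]  # +2: header + 1-based
            raise SchemaError(
                f"{path.name}: non-numeric {col!r} at line(s) {lines}"
            )
        numeric[CORE_COLUMNS[col]] = vals.to_numpy(dtype=float)
    depth = numeric.pop("depth")
    if np.any(~np.isfinite(depth)):
        raise SchemaError(f"{path.name}: missing depth value")
    if np.any(np.diff(depth) <= 0):
        raise ValidationError(
            f"{path.name}: depths must be strictly increasing (duplicates?)"
        )
    return CoreProfile(station_id=station_id or path.stem, depth=depth,
                       **numeric)


def write_solidphase(profile: SolidPhaseProfile, path) -> None:
    pd.DataFrame({
        "depth_cmbsf": profile.depth,
        "tc_wt": profile.tc,
        "tic_wt": profile.tic,
        "tn_wt": profile.tn,
    }).to_csv(path, index=False)


def read_solidphase(path, station_id: Optional[str] = None) -> SolidPhaseProfile:
    path = Path(path)
    df = pd.read_csv(path)
    for col in SOLID_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing mandatory column {col!r}")
    return SolidPhaseProfile(
        station_id=station_id or path.stem,
        depth=df["depth_cmbsf"].to_numpy(float),
        tc=df["tc_wt"].to_numpy(float),
        tic=df["tic_wt"].to_numpy(float),
        tn=df["tn_wt"].to_numpy(float),
    )


# ---------------------------------------------------------------------------
# taxonomy tables (RDP fixrank-style TSV) and SRB profiles
# ---------------------------------------------------------------------------

def write_taxonomy_table(table: TaxonomyTable, path) -> None:
    rows = [{"otu_id": r.otu_id, "read_count": r.read_count,
             "lineage": r.lineage.to_string()} for r in table.records]
    pd.DataFrame(rows, columns=["otu_id", "read_count", "lineage"]).to_csv(
        path, sep="\t", index=False)


def read_taxonomy_table(path, station_id: str, depth: float) -> TaxonomyTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("otu_id", "read_count", "lineage"):
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing column {col!r}")
    records = []
    for i, row in df.iterrows():
        try:
            reads = int(row["read_count"])
        except (TypeError, ValueError):
            raise SchemaError(
                f"{path.name}: non-integer read_count at line {i + 2}"
            )
        records.append(OtuRecord(str(row["otu_id"]),
                                 Lineage.from_string(row["lineage"]), reads))
    return TaxonomyTable(station_id=station_id, depth=depth, records=records)


def write_taxonomy_set(tables: Sequence[TaxonomyTable], outdir,
                       station_tag: Optional[str] = None) -> Path:
    """Write one TSV per depth plus a manifest CSV; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for t in tables:
        tag = station_tag or t.station_id.replace("/", "_")
        fname = f"{tag}_d{t.depth:07.2f}.tsv"
        write_taxonomy_table(t, outdir / fname)
        rows.append({"file": fname, "station_id": t.station_id,
                     "depth_cmbsf": t.depth})
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_taxonomy_set(manifest_path) -> List[TaxonomyTable]:
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    base = manifest_path.parent
    tables = []
    for _, row in df.iterrows():
        tables.append(read_taxonomy_table(base / row["file"],
                                          str(row["station_id"]),
                                          float(row["depth_cmbsf"])))
    return tables


def write_srb_profile(profile: SrbDepthProfile, path) -> None:
    pd.DataFrame({
        "depth_cmbsf": profile.depths,
        "srb_otus": profile.srb_count,
        "normalized": profile.normalized,
    }).to_csv(path, index=False)


def read_srb_profile(path, station_id: Optional[str] = None) -> SrbDepthProfile:
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("depth_cmbsf", "srb_otus"):
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing column {col!r}")
    return SrbDepthProfile(
        station_id=station_id or path.stem,
        depths=df["depth_cmbsf"].to_numpy(float),
        srb_count=df["srb_otus"].to_numpy(int),
    )


def write_truth(truth: dict, path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True))


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text())


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# transect report
# ---------------------------------------------------------------------------

def run_report(config: RunConfig, cores) -> tuple:
    """One summary row per station, ordered by water depth, plus a JSON-able
    run-record echoing every setting.

    ``cores`` are SyntheticCore-like objects (spec/porewater/solidphase/
    taxonomy).  Per-core failures are isolated: the failing station's row
    carries an ``error`` note instead of aborting the transect.
    """
    rows = []
    for core in cores:
        spec = core.spec
        row = {
            "station_id": spec.station_id,
            "water_depth_mbsl": spec.water_depth,
            "bottom_water_o2_uM": spec.bottom_water_o2,
            "error": "",
        }
        try:
            row["mean_toc_wt"] = float(np.mean(core.solidphase.toc))
            params = FluxParameters(
                porosity=spec.porosity,
                bottom_water_temp=spec.bottom_water_temp,
                tortuosity_exponent=config.tortuosity_exponent,
                do_intercept=config.do_intercept,
                do_slope=config.do_slope,
            )
            flux = geochem.compute_flux(core.porewater, params)
            row["dcdx_mM_cm"] = flux.gradient.dcdx
            row["j_so4_mmol_cm2_yr"] = flux.flux
            smtz = geochem.detect_smtz(core.porewater,
                                       config.sulfate_floor,
                                       config.methane_rise_factor)
            row["smtz_upper_cm"] = smtz.upper_depth if smtz.found else np.nan
            row["smtz_lower_cm"] = smtz.lower_depth if smtz.found else np.nan
            profile = srb.build_srb_profile(core.taxonomy)
            row["srb_otus_max"] = int(profile.max_count)
            row["srb_otus_mean"] = float(np.mean(profile.srb_count))
            seg = zones.segment_and_fit(profile, mode=config.zone_mode)
            for name, fit in (("decay", seg.decay), ("gaussian", seg.gaussian),
                              ("growth", seg.growth)):
                row[f"zone_{name}_chi2"] = fit.chi2 if fit else np.nan
        except Exception as exc:  # noqa: BLE001 - isolate per-core failures
            log.warning("station %s failed: %s", spec.station_id, exc)
            row["error"] = str(exc)
        rows.append(row)
    report = pd.DataFrame(rows).sort_values("water_depth_mbsl",
                                            ignore_index=True)
    record = {
        "config": config.to_dict(),
        "stations": [r["station_id"] for r in rows],
        "package": "omzsed",
    }
    return report, record
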