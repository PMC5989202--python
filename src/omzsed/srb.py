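"""Sulfate-reducing bacteria (SRB) diversity from OTU taxonomy tables.

Consumes RDP-classifier-style taxonomy tables (one row per OTU: id, read
count, semicolon-ranked lineage), applies the dissimilatory sulfate-reducer
taxon filter (15 genera plus 6 deltaproteobacterial families; bacteria
only), removes singleton OTUs, builds per-core SRB-OTU depth profiles with
within-core max-normalization, and computes rarefaction expectations and
the ACE richness estimator.

The taxon filter matches on exact rank names, case-insensitively: the
genus list governs the genus rank and the family list the family rank, so
e.g. Desulfovibrionaceae (family) does not match through the genus list
and vice versa.  Archaeal lineages are never counted as SRB, mirroring an
analysis restricted to bacterial 16S data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence

import numpy as np
from scipy.special import gammaln

log = logging.getLogger(__name__)

#: Genera whose members are all dissimilatory sulfate reducers.
SRB_GENERA = frozenset(g.lower() for g in (
    "Desulfacinum", "Desulfobacca", "Desulfobaculum", "Desulfocurvus",
    "Desulfoglaeba", "Desulfomonas", "Desulfomonile", "Desulforhabdus",
    "Desulfosoma", "Desulfovibrio", "Desulfovirga", "Desulfurella",
    "Desulfuromonas", "Desulfuromusa", "Thermodesulforhabdus",
))

#: Deltaproteobacterial families counted as SRB in their entirety.
SRB_FAMILIES = frozenset(f.lower() for f in (
    "Desulfarculaceae", "Desulfobacteraceae", "Desulfobulbaceae",
    "Desulfohalobiaceae", "Desulfomicrobiaceae", "Desulfonatronaceae",
))

RANKS = ("domain", "phylum", "class", "order", "family", "genus")


class TaxonomyError(ValueError):
    """Raised for malformed taxonomy tables or ordering-contract violations."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Lineage:
    """Ranked taxonomic lineage, domain through genus; missing ranks empty."""

    domain: str = ""
    phylum: str = ""
    klass: str = ""
    order: str = ""
    family: str = ""
    genus: str = ""

    @classmethod
    def from_string(cls, text: str) -> "Lineage":
        """Parse a semicolon-delimited ranked string (RDP fixrank dialect).

        Confidence annotations in parentheses, e.g. ``Desulfovibrio(100)``,
        are stripped.  Unparseable input yields an all-empty lineage.
        """
        if not isinstance(text, str) or not text.strip():
            log.info("unparseable lineage %r treated as unclassified", text)
            return cls()
        parts = [p.strip() for p in text.split(";")]
        clean = []
        for p in parts[: len(RANKS)]:
            if "(" in p:
                p = p[: p.index("(")].strip()
            clean.append(p)
        clean += [""] * (len(RANKS) - len(clean))
        return cls(*clean)

    def to_string(self) -> str:
        return ";".join([self.domain, self.phylum, self.klass,
                         self.order, self.family, self.genus])


@dataclass(frozen=True)
class OtuRecord:
    otu_id: str
    lineage: Lineage
    read_count: int

    def __post_init__(self):
        if self.read_count < 1:
            raise TaxonomyError(
                f"OTU {self.otu_id}: read_count must be >= 1"
            )


@dataclass
class TaxonomyTable:
    """OTU inventory for one sediment datapoint (station x depth)."""

    station_id: str
    depth: float  # cmbsf
    records: List[OtuRecord]
    sra_run_accession: Optional[str] = None
    singletons_removed: bool = False

    def __post_init__(self):
        ids = [r.otu_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise TaxonomyError(
                f"{self.station_id}@{self.depth}: duplicate OTU ids"
            )

    @property
    def n_otus(self) -> int:
        return len(self.records)

    @property
    def total_reads(self) -> int:
        return sum(r.read_count for r in self.records)

    def read_counts(self) -> np.ndarray:
        return np.array([r.read_count for r in self.records], dtype=int)


@dataclass
class SrbDepthProfile:
    """Raw and max-normalized SRB-OTU counts against depth for one core."""

    station_id: str
    depths: np.ndarray
    srb_count: np.ndarray
    normalized: np.ndarray = field(init=False)
    max_count: int = field(init=False)

    def __post_init__(self):
        self.depths = np.asarray(self.depths, dtype=float)
        self.srb_count = np.asarray(self.srb_count, dtype=int)
        if self.depths.shape != self.srb_count.shape:
            raise TaxonomyError("depths and counts must align")
        if not np.all(np.diff(self.depths) > 0):
            raise TaxonomyError("depths must be strictly increasing")
        if np.any(self.srb_count < 0):
            raise TaxonomyError("negative SRB count")
        self.max_count = int(self.srb_count.max()) if self.srb_count.size else 0
        if self.max_count == 0:
            raise TaxonomyError(
                f"{self.station_id}: all-zero SRB profile cannot be normalized"
            )
        self.normalized = self.srb_count / self.max_count


# ---------------------------------------------------------------------------
# filtering and counting
# ---------------------------------------------------------------------------

def is_srb_lineage(lineage: Lineage) -> bool:
    """True iff the lineage belongs to a known dissimilatory sulfate reducer.

    Genus match against the 15-genus list, or family match against the six
    deltaproteobacterial families; archaeal lineages are always excluded
    (archaeal sulfate reducers such as Archaeoglobus are out of scope of a
    bacterial 16S survey).
    """
    if lineage.domain.strip().lower() == "archaea":
        return False
    if lineage.genus.strip().lower() in SRB_GENERA:
        return True
    if lineage.family.strip().lower() in SRB_FAMILIES:
        return True
    return False


def remove_singletons(table: TaxonomyTable) -> TaxonomyTable:
    """Drop every OTU represented by a single read; record order preserved."""
    kept = [r for r in table.records if r.read_count > 1]
    return TaxonomyTable(
        station_id=table.station_id,
        depth=table.depth,
        records=kept,
        sra_run_accession=table.sra_run_accession,
        singletons_removed=True,
    )


def srb_otu_count(table: TaxonomyTable) -> int:
    """Number of SRB-affiliated OTUs in a singleton-filtered table.

    Refuses tables that have not been singleton-filtered: the enumeration
    is defined on the filtered OTU set, and the contract is enforced rather
    than silently assumed.
    """
    if not table.singletons_removed:
        raise TaxonomyError(
            "srb_otu_count requires a singleton-filtered table; "
            "apply remove_singletons first"
        )
    return sum(1 for r in table.records if is_srb_lineage(r.lineage))


def build_srb_profile(tables: Sequence[TaxonomyTable],
                      station_id: Optional[str] = None) -> SrbDepthProfile:
    """Per-core SRB-OTU depth profile from one table per sediment datapoint.

    Singleton removal is applied to any table not already filtered.
    """
    if not tables:
        raise TaxonomyError("no taxonomy tables supplied")
    station = station_id or tables[0].station_id
    pairs = []
    for t in tables:
        if t.station_id != station:
            raise TaxonomyError(
                f"mixed stations in profile: {t.station_id} vs {station}"
            )
        ft = t if t.singletons_removed else remove_singletons(t)
        pairs.append((t.depth, srb_otu_count(ft)))
    pairs.sort(key=lambda p: p[0])
    depths = np.array([p[0] for p in pairs])
    counts = np.array([p[1] for p in pairs])
    return SrbDepthProfile(station_id=station, depths=depths, srb_count=counts)


def normalize_profile(counts: Sequence[int],
                      depths: Optional[Sequence[float]] = None,
                      station_id: str = "core") -> SrbDepthProfile:
    """Max-normalize per-depth SRB counts into an SrbDepthProfile.

    normalized_i = count_i / max_j(count_j); undefined (error) when every
    depth has zero SRB OTUs.
    """
    counts = np.asarray(counts, dtype=int)
    if depths is None:
        depths = np.arange(counts.size, dtype=float)
    return SrbDepthProfile(station_id=station_id, depths=np.asarray(depths),
                           srb_count=counts)


# ---------------------------------------------------------------------------
# richness statistics
# ---------------------------------------------------------------------------

def rarefaction_expectation(otu_read_counts: Sequence[int],
                            subsample_size: int) -> float:
    """Expected OTU richness in a random subsample of ``subsample_size`` reads.

    Hypergeometric expectation E[S] = sum_i [1 - C(N - N_i, m) / C(N, m)],
    evaluated with log-gamma binomials for numerical stability.
    """
    counts = np.asarray(otu_read_counts, dtype=int)
    if counts.size and counts.min() < 1:
        raise TaxonomyError("read counts must be >= 1")
    n_total = int(counts.sum())
    m = int(subsample_size)
    if not 0 <= m <= n_total:
        raise TaxonomyError(
            f"subsample size {m} outside [0, {n_total}]"
        )
    if m == 0 or counts.size == 0:
        return 0.0

    def log_choose(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    expected = 0.0
    log_denom = log_choose(n_total, m)
    for ni in counts:
        if n_total - ni < m:
            expected += 1.0  # OTU i always sampled
        else:
            expected += 1.0 - math.exp(log_choose(n_total - ni, m) - log_denom)
    return expected


def rarefaction_curve(otu_read_counts: Sequence[int],
                      step: int = 1) -> np.ndarray:
    """(m, E[S]) pairs from 0 to the total read count in increments of step."""
    n_total = int(np.sum(otu_read_counts))
    ms = list(range(0, n_total + 1, step))
    if ms[-1] != n_total:
        ms.append(n_total)
    return np.array([(m, rarefaction_expectation(otu_read_counts, m))
                     for m in ms])


def chao1_estimate(otu_read_counts: Sequence[int]) -> float:
    """Chao1 richness (bias-corrected form), fallback for degenerate ACE."""
    counts = np.asarray(otu_read_counts, dtype=int)
    s_obs = counts.size
    f1 = int(np.sum(counts == 1))
    f2 = int(np.sum(counts == 2))
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def ace_estimate(otu_read_counts: Sequence[int],
                 rare_threshold: int = 10) -> float:
    """Abundance-based coverage estimator (ACE) of OTU richness.

    S_ace = S_abund + S_rare / C_ace + (F1 / C_ace) * gamma^2, where
    C_ace = 1 - F1 / N_rare is the rare-class sample coverage and gamma^2
    the rare-class coefficient of variation, floored at zero.  When every
    rare read is a singleton (C_ace = 0) the estimator is undefined and
    Chao1 is returned instead, with a log notice.
    """
    counts = np.asarray(otu_read_counts, dtype=int)
    if counts.size == 0:
        return 0.0
    if counts.min() < 1:
        raise TaxonomyError("read counts must be >= 1")
    rare = counts[counts <= rare_threshold]
    s_abund = int(np.sum(counts > rare_threshold))
    s_rare = rare.size
    if s_rare == 0:
        return float(s_abund)
    n_rare = int(rare.sum())
    f1 = int(np.sum(rare == 1))
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        log.info("ACE undefined (all rare reads are singletons); "
                 "falling back to Chao1")
        return chao1_estimate(counts)
    freq_sum = sum(i * (i - 1) * int(np.sum(rare == i))
                   for i in range(1, rare_threshold + 1))
    gamma_sq = max(
        (s_rare / c_ace) * freq_sum / (n_rare * (n_rare - 1)) - 1.0, 0.0
    ) if n_rare > 1 else 0.0
    return s_abund + s_rare / c_ace + (f1 / c_ace) * gamma_sq
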