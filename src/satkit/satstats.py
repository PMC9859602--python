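"""Per-family satellitome statistics.

For each satellite family masked in a read sample this module computes the
field's standard descriptors:

* genome proportion — percent of sampled bp aligned to the family
  ("read percentages");
* divergence landscape — abundance binned by integer K2P divergence,
  the histogram whose shape distinguishes recently expanded
  (leptokurtic), decaying (mesokurtic) and degenerated (platykurtic)
  families;
* TSI (tandem structure index) — fraction of family-aligned reads whose
  alignment spans at least 89% of the read, a proxy for array
  clusterization;
* DivPeak — the landscape's modal divergence bin (degeneration proxy);
* RSP — fraction of the family's abundance within +/-2 divergence points
  of DivPeak (homogenization proxy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .repeat_align import MaskResult

__all__ = [
    "Landscape",
    "FamilyStats",
    "SatellitomeTable",
    "genome_proportion",
    "landscape",
    "tsi",
    "divpeak",
    "rsp",
    "classify_landscape",
    "family_stats",
    "satellitome_table",
    "summarize_table",
    "load_table1_fixture",
    "INTERNAL_READ_FRACTION",
]

#: Minimum fraction of the read length that must align for the read to count
#: as an internal (pure satellite) read in the TSI.
INTERNAL_READ_FRACTION = 0.89

#: Half-width, in integer divergence bins, of the RSP peak window.
RSP_WINDOW = 2

SUMMARY_COLUMNS = ["monomer_length", "at_percent", "mean_k2p", "tsi", "divpeak", "rsp"]


@dataclass
class Landscape:
    """Family abundance binned by integer K2P divergence (floor of percent)."""

    family: str
    bins: dict[int, float] = field(default_factory=dict)

    @property
    def total_abundance(self) -> float:
        return sum(self.bins.values())

    def __bool__(self) -> bool:
        return bool(self.bins)


@dataclass
class FamilyStats:
    """Table-row statistics for one family."""

    name: str
    genome_proportion: float  # percent
    monomer_length: int
    at_percent: float
    mean_k2p: float | None  # percent, bp-weighted over alignments
    tsi: float | None
    divpeak: int | None
    rsp: float | None
    label: str | None = None


@dataclass
class SatellitomeTable:
    """Per-family rows plus recomputable summary statistics."""

    rows: list[FamilyStats]

    @property
    def total_proportion(self) -> float:
        return sum(r.genome_proportion for r in self.rows)

    def summary(self) -> dict[str, dict[str, float]]:
        return summarize_table(self.to_dataframe())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "name": r.name,
                    "genome_proportion": r.genome_proportion,
                    "monomer_length": r.monomer_length,
                    "at_percent": r.at_percent,
                    "mean_k2p": r.mean_k2p,
                    "tsi": r.tsi,
                    "divpeak": r.divpeak,
                    "rsp": r.rsp,
                    "label": r.label,
                }
                for r in self.rows
            ]
        )


def genome_proportion(mask_result: MaskResult, family: str) -> float:
    """Percent of sampled bp aligned to the family."""
    if mask_result.total_sampled_bp <= 0:
        raise ValueError("total_sampled_bp must be positive")
    bp = sum(r.bp_weight for r in mask_result.by_family(family))
    return 100.0 * bp / mask_result.total_sampled_bp


def landscape(mask_result: MaskResult, family: str) -> Landscape:
    """Divergence landscape: each alignment contributes its credited bp
    (as percent of sampled bp) to bin ``floor(k2p %)``."""
    bins: dict[int, float] = {}
    denom = mask_result.total_sampled_bp
    for rec in mask_result.by_family(family):
        b = int(math.floor(rec.k2p_divergence))
        bins[b] = bins.get(b, 0.0) + 100.0 * rec.bp_weight / denom
    return Landscape(family=family, bins=bins)


def tsi(mask_result: MaskResult, family: str) -> float | None:
    """Tandem structure index: internal reads / all reads aligned to the family.

    A read is internal when a single alignment covers at least 89% of its
    length; a read with only partial hits counts once, as external. Returns
    ``None`` (missing, not 0) when no read aligns to the family.
    """
    internal: set[str] = set()
    seen: set[str] = set()
    for rec in mask_result.by_family(family):
        seen.add(rec.read_id)
        if rec.read_span_bp >= INTERNAL_READ_FRACTION * rec.read_length:
            internal.add(rec.read_id)
    if not seen:
        return None
    return len(internal) / len(seen)


def divpeak(ls: Landscape) -> int:
    """Divergence bin where the landscape is maximal (ties: smallest bin)."""
    if not ls.bins:
        raise ValueError(f"empty landscape for family {ls.family}")
    peak = max(ls.bins.items(), key=lambda kv: (kv[1], -kv[0]))
    return peak[0]


def rsp(ls: Landscape, peak: int) -> float:
    """Relative peak size: abundance within +/-2 bins of the peak (window
    truncated at bin 0) over the family's total abundance."""
    total = ls.total_abundance
    if total == 0:
        raise ValueError(f"zero total abundance for family {ls.family}")
    lo = max(0, peak - RSP_WINDOW)
    hi = peak + RSP_WINDOW
    return sum(v for b, v in ls.bins.items() if lo <= b <= hi) / total


def classify_landscape(
    ls: Landscape,
    rsp_lepto: float = 0.8,
    rsp_platy: float = 0.3,
    divpeak_lepto: int = 5,
    divpeak_platy: int = 15,
) -> str:
    """Classify a landscape as leptokurtic / mesokurtic / platykurtic.

    Leptokurtic (recent expansion): high RSP at a low-divergence peak.
    Platykurtic (degenerated): low RSP at a high-divergence peak. The
    numeric thresholds operationalize qualitative usage and are exposed.
    """
    peak = divpeak(ls)
    r = rsp(ls, peak)
    return classify_from_stats(peak, r, rsp_lepto, rsp_platy, divpeak_lepto, divpeak_platy)


def classify_from_stats(
    peak: int,
    r: float,
    rsp_lepto: float = 0.8,
    rsp_platy: float = 0.3,
    divpeak_lepto: int = 5,
    divpeak_platy: int = 15,
) -> str:
    if r >= rsp_lepto and peak <= divpeak_lepto:
        return "leptokurtic"
    if r <= rsp_platy and peak >= divpeak_platy:
        return "platykurtic"
    return "mesokurtic"


def family_stats(mask_result: MaskResult, fam) -> FamilyStats:
    """All Table-row statistics for one :class:`~satkit.seqcore.SatFamily`."""
    ls = landscape(mask_result, fam.name)
    prop = genome_proportion(mask_result, fam.name)
    if ls:
        peak = divpeak(ls)
        r = rsp(ls, peak)
        recs = mask_result.by_family(fam.name)
        w = sum(rec.bp_weight for rec in recs)
        mean_k2p = sum(rec.k2p_divergence * rec.bp_weight for rec in recs) / w
        label = classify_from_stats(peak, r)
    else:
        peak = r = mean_k2p = label = None
    return FamilyStats(
        name=fam.name,
        genome_proportion=prop,
        monomer_length=fam.monomer_length,
        at_percent=100.0 * fam.at_fraction,
        mean_k2p=mean_k2p,
        tsi=tsi(mask_result, fam.name),
        divpeak=peak,
        rsp=r,
        label=label,
    )


def satellitome_table(mask_result: MaskResult, library) -> SatellitomeTable:
    """Per-family statistics for every family of a library, in rank order."""
    return SatellitomeTable(rows=[family_stats(mask_result, fam) for fam in library])


def summarize_table(
    rows: pd.DataFrame | Sequence[FamilyStats],
    columns: Iterable[str] = SUMMARY_COLUMNS,
) -> dict[str, dict[str, float]]:
    """Mean / sample SD / median per numeric column.

    Sample SD uses n-1 degrees of freedom (0 by convention for a single
    row); the median is the middle order statistic, or the midpoint of the
    two middle values for even n. Values are returned unrounded; rounding
    to 2 decimals happens at the report layer.
    """
    if not isinstance(rows, pd.DataFrame):
        rows = SatellitomeTable(rows=list(rows)).to_dataframe()
    if len(rows) < 1:
        raise ValueError("need at least one row")
    out: dict[str, dict[str, float]] = {}
    for col in columns:
        vals = rows[col].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            continue
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        out[col] = {
            "mean": float(np.mean(vals)),
            "sd": sd,
            "median": float(np.median(vals)),
        }
    return out


def load_table1_fixture() -> pd.DataFrame:
    """The packaged 17-entry published satellitome table for *T. aquitania*
    (TaquSat4 as two monomer-length variants; telomeric repeat included)."""
    with resources.files("satkit.data").joinpath("taqu_table1.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
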