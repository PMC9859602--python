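"""Tandem-repeat period detection and family naming.

A quantitative stand-in for visual dotplot inspection of repetitive
contigs: the monomer period is the lag maximizing mean base identity
between the contig and itself shifted, and the consensus monomer is the
column majority over the stacked period-length windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .seqcore import SatFamily, SatLibrary

__all__ = [
    "PeriodCall",
    "detect_period",
    "extract_and_stack",
    "canonical_rotation",
    "name_families",
]


@dataclass
class PeriodCall:
    """Detected tandem period of a contig."""

    contig_id: str
    period: int
    identity_at_period: float
    phase: int = 0


def detect_period(
    contig: str,
    min_period: int = 1,
    max_period: int | None = None,
    contig_id: str = "contig",
    min_identity: float = 0.6,
) -> PeriodCall | None:
    """Detect the fundamental tandem period of a contig.

    For each candidate lag p the mean identity between ``contig[i]`` and
    ``contig[i+p]`` is computed; the call is the smallest p within 0.01
    identity of the maximum (the fundamental period rather than one of its
    multiples). Returns ``None`` when the best identity is below
    ``min_identity`` (no tandem structure).
    """
    n = len(contig)
    if max_period is None:
        max_period = n // 3
    max_period = min(max_period, n - 1)
    if max_period < min_period:
        raise ValueError("contig too short for the requested period range")
    arr = np.frombuffer(contig.upper().encode(), dtype=np.uint8)
    periods = np.arange(min_period, max_period + 1)
    identities = np.empty(periods.size)
    for i, p in enumerate(periods):
        identities[i] = float((arr[:-p] == arr[p:]).mean())
    best = float(identities.max())
    if best < min_identity:
        return None
    fundamental = int(periods[np.argmax(identities >= best - 0.01)])
    ident = float(identities[fundamental - min_period])
    return PeriodCall(contig_id=contig_id, period=fundamental, identity_at_period=ident)


def extract_and_stack(contig: str, period: int, phase: int = 0) -> list[str]:
    """Cut a contig into consecutive period-length windows starting at phase.

    The trailing partial window is dropped; the stack feeds
    :func:`satkit.seqcore.majority_consensus`.
    """
    if period < 1:
        raise ValueError("period must be >= 1")
    if not 0 <= phase < period:
        raise ValueError("phase must lie in [0, period)")
    return [
        contig[i : i + period]
        for i in range(phase, len(contig) - period + 1, period)
    ]


def canonical_rotation(monomer: str) -> str:
    """Lexicographically smallest rotation; makes family comparison
    invariant to the arbitrary start point of a tandem array."""
    if not monomer:
        raise ValueError("empty monomer")
    return min(monomer[i:] + monomer[:i] for i in range(len(monomer)))


def name_families(
    families: Sequence[tuple[str, float]], species_tag: str
) -> SatLibrary:
    """Name families ``<tag>Sat<rank>-<length>`` by decreasing proportion.

    ``families`` is a sequence of (monomer, genome proportion). Ties in
    proportion are broken by longer monomer first, then lexicographically
    by monomer sequence.
    """
    ordered = sorted(families, key=lambda t: (-t[1], -len(t[0]), t[0]))
    out = []
    for rank, (monomer, _prop) in enumerate(ordered, start=1):
        out.append(
            SatFamily(
                name=f"{species_tag}Sat{rank}-{len(monomer)}",
                rank=rank,
                monomer=monomer,
            )
        )
    names = [f.name for f in out]
    if len(set(names)) != len(names):
        raise ValueError("duplicate family names produced")
    return SatLibrary(families=out, species_tag=species_tag)
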