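"""Sequence primitives for satellitome analysis.

Sequences are plain uppercase strings over the IUPAC nucleotide alphabet.
Coordinates are 0-based half-open everywhere inside the package; conversion
to 1-based inclusive happens only in report writers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "SatFamily",
    "SatLibrary",
    "read_fasta",
    "write_fasta",
    "at_content",
    "reverse_complement",
    "build_reference",
    "telomeric_reference",
    "majority_consensus",
    "read_library_tsv",
    "write_library_tsv",
]

IUPAC = set("ACGTRYSWKMBDHVN")
GAP = "-"

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN",
    "TGCAYRSWMKVHDBN",
)

#: Telomeric repeat motif of vertebrates.
TELOMERE_MOTIF = "TTAGGG"


class FastaParseError(ValueError):
    """Raised when a FASTA file violates the format; carries the line number."""


@dataclass
class SatFamily:
    """A named satellite DNA family: consensus monomer plus naming metadata.

    Families are named ``<tag>Sat<rank>-<monomer_length>`` with rank 1 the
    most abundant family of the satellitome.
    """

    name: str
    rank: int
    monomer: str
    monomer_length: int = field(default=0)
    at_fraction: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        self.monomer = self.monomer.upper()
        if len(self.monomer) < 1:
            raise ValueError("monomer must be non-empty")
        if self.rank < 1:
            raise ValueError("rank must be a positive integer")
        if self.monomer_length and self.monomer_length != len(self.monomer):
            raise ValueError(
                f"monomer_length {self.monomer_length} != len(monomer) {len(self.monomer)}"
            )
        self.monomer_length = len(self.monomer)
        at = at_content(self.monomer)
        if not math.isnan(self.at_fraction) and abs(self.at_fraction - at) > 1e-6:
            raise ValueError("at_fraction inconsistent with monomer")
        self.at_fraction = at


@dataclass
class SatLibrary:
    """Ordered collection of satellite families for one species.

    Ranks must be 1..N without gaps; ordering follows decreasing genome
    proportion when proportions are known.
    """

    families: list[SatFamily]
    species_tag: str = ""

    def __post_init__(self) -> None:
        ranks = sorted(f.rank for f in self.families)
        if ranks != list(range(1, len(self.families) + 1)):
            raise ValueError(f"family ranks must be 1..N without gaps, got {ranks}")
        names = [f.name for f in self.families]
        if len(set(names)) != len(names):
            raise ValueError("duplicate family names in library")
        self.families = sorted(self.families, key=lambda f: f.rank)

    def __iter__(self):
        return iter(self.families)

    def __len__(self) -> int:
        return len(self.families)

    def __getitem__(self, name: str) -> SatFamily:
        for fam in self.families:
            if fam.name == name:
                return fam
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.families]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (multi-)FASTA file into ``[(id, SEQUENCE), ...]``.

    Sequences are uppercased; IUPAC ambiguity codes are preserved; record
    order is preserved. The record id is the first whitespace-delimited
    token of the header.
    """
    path = Path(path)
    # Light structural validation so errors carry a line number; the actual
    # record parsing is Biopython's.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path}:{lineno}: sequence data before first '>' header"
                )
            break
    records = []
    with open(path) as fh:
        for header, seq in SimpleFastaParser(fh):
            records.append((header.split()[0] if header else "", seq.upper()))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA with fixed-width line wrapping."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def at_content(seq: str) -> float:
    """A+T fraction over unambiguous bases only.

    Ambiguity codes are excluded from both numerator and denominator.
    Raises ``ValueError`` when the sequence has no unambiguous base.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    at = seq.count("A") + seq.count("T")
    acgt = at + seq.count("C") + seq.count("G")
    if acgt == 0:
        raise ValueError("sequence has no unambiguous A/C/G/T bases")
    return at / acgt


def reverse_complement(seq: str) -> str:
    """Reverse complement under the full IUPAC alphabet."""
    seq = seq.upper()
    bad = set(seq) - IUPAC
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def build_reference(monomer: str, target_len: int = 200) -> str:
    """Build the alignment reference for a monomer: a dimer, or for short
    monomers the smallest whole-number tiling reaching ``target_len``.

    A monomer counts as short when its length is below ``target_len / 2``;
    then ``ceil(target_len / len)`` copies are concatenated (length in
    ``[target_len, target_len + len)``). Otherwise exactly two copies.
    """
    m = len(monomer)
    if m < 1:
        raise ValueError("monomer must be non-empty")
    if m >= target_len / 2:
        return monomer * 2
    return monomer * math.ceil(target_len / m)


def telomeric_reference(n_copies: int = 50) -> str:
    """The (TTAGGG)_n telomeric repeat used as an extra library entry."""
    return TELOMERE_MOTIF * n_copies


def majority_consensus(aligned_monomers: Sequence[str]) -> str:
    """Per-column majority consensus of pre-stacked, equal-length rows.

    Columns where the gap symbol is the strict majority are dropped. Ties
    between bases are broken by fixed order A < C < G < T; a base beats the
    gap on a tie.
    """
    if not aligned_monomers:
        raise ValueError("no rows given")
    if len(aligned_monomers) < 2:
        raise ValueError("need at least 2 rows for a consensus")
    width = len(aligned_monomers[0])
    if any(len(r) != width for r in aligned_monomers):
        raise ValueError("rows must have equal length")
    rows = [r.upper() for r in aligned_monomers]
    out = []
    for col in range(width):
        column = [r[col] for r in rows]
        gap_n = column.count(GAP)
        best_base, best_n = "", -1
        for base in "ACGT":
            n = column.count(base)
            if n > best_n:
                best_base, best_n = base, n
        if gap_n > best_n:
            continue
        out.append(best_base)
    return "".join(out)


def read_library_tsv(path: str | Path, species_tag: str = "") -> SatLibrary:
    """Read a family library from TSV (name, rank, monomer_length, at_fraction, monomer)."""
    families = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            families.append(
                SatFamily(
                    name=parts[idx["name"]],
                    rank=int(parts[idx["rank"]]),
                    monomer=parts[idx["monomer"]],
                )
            )
    return SatLibrary(families=families, species_tag=species_tag)


def write_library_tsv(library: SatLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("name\trank\tmonomer_length\tat_fraction\tmonomer\n")
        for fam in library:
            fh.write(
                f"{fam.name}\t{fam.rank}\t{fam.monomer_length}\t"
                f"{fam.at_fraction:.6f}\t{fam.monomer}\n"
            )
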