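"""Synthetic genomes with tandem satellite arrays, plus sheared reads.

The generator emulates low-coverage shotgun data from a genome carrying
satellite DNA families: tandem arrays of a consensus monomer are embedded in
AT-rich random background, each monomer copy independently mutated from the
consensus under the Kimura 2-parameter substitution model (star phylogeny).
Array count and length dispersion control the clusterization level that the
tandem structure index responds to; per-"species" abundance multipliers model
the library hypothesis, under which related species share a common pool of
families at lineage-specific abundances.

All randomness flows from a single integer seed through
``numpy.random.Generator``; every operation is reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .seqcore import reverse_complement

__all__ = [
    "FamilySimSpec",
    "SimSpec",
    "TruthRow",
    "TruthTable",
    "ReadSet",
    "generate_background",
    "mutate_monomer",
    "k2p_site_probabilities",
    "build_genome",
    "shear_reads",
    "simulate_species_set",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
# transition partner by base index (A<->G, C<->T)
_TRANSITION = np.array([2, 3, 0, 1], dtype=np.uint8)
# the two transversion partners by base index
_TRANSVERSION = np.array([[1, 3], [0, 2], [1, 3], [0, 2]], dtype=np.uint8)


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        out[arr == b] = i
    if (out == 255).any():
        raise ValueError("simulator input must be over {A,C,G,T}")
    return out


def _decode(idx: np.ndarray) -> str:
    return _BASES[idx].tobytes().decode()


@dataclass
class FamilySimSpec:
    """Generative parameters of one satellite family.

    divergence is the expected per-site K2P distance of each copy from the
    consensus (fraction, not percent); kappa the transition/transversion
    rate ratio; n_arrays and array_length_cv control clusterization (array
    lengths drawn from a gamma distribution with that coefficient of
    variation, minimum one monomer).
    """

    monomer: str
    target_proportion: float
    divergence: float = 0.05
    kappa: float = 2.0
    n_arrays: int = 3
    array_length_cv: float = 0.5
    indel_rate: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        self.monomer = self.monomer.upper()
        if not (0.0 <= self.divergence <= 0.35):
            raise ValueError("family divergence must lie in [0, 0.35]")
        if not (0.0 < self.target_proportion < 1.0):
            raise ValueError("target_proportion must lie in (0, 1)")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.n_arrays < 1:
            raise ValueError("n_arrays must be >= 1")


@dataclass
class SimSpec:
    """A full synthetic-genome specification."""

    genome_length: int
    families: list[FamilySimSpec]
    background_at: float = 0.59
    read_length: int = 150
    coverage: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.read_length > self.genome_length:
            raise ValueError("read_length must not exceed genome_length")
        if sum(f.target_proportion for f in self.families) >= 1.0:
            raise ValueError("family proportions must sum to < 1")
        for i, fam in enumerate(self.families):
            if not fam.name:
                fam.name = f"fam{i + 1}"


@dataclass
class TruthRow:
    """Ground truth for one family in one simulated genome."""

    name: str
    true_bp: int
    true_proportion: float
    realized_divergence: float
    intervals: list[tuple[str, int, int]] = field(default_factory=list)


@dataclass
class TruthTable:
    """Per-family ground truth emitted alongside a simulated genome."""

    genome_length: int
    rows: dict[str, TruthRow]

    def __getitem__(self, name: str) -> TruthRow:
        return self.rows[name]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# genome_length={self.genome_length}\n")
            fh.write("name\ttrue_bp\ttrue_proportion\trealized_divergence\tintervals\n")
            for row in self.rows.values():
                ivals = ";".join(f"{c}:{s}-{e}" for c, s, e in row.intervals)
                fh.write(
                    f"{row.name}\t{row.true_bp}\t{row.true_proportion:.8f}\t"
                    f"{row.realized_divergence:.6f}\t{ivals}\n"
                )


@dataclass
class ReadSet:
    """Sheared single-end reads with bookkeeping for abundance denominators."""

    reads: list[tuple[str, str]]
    total_bp: int
    read_length: int

    def __iter__(self):
        return iter(self.reads)

    def __len__(self) -> int:
        return len(self.reads)

    def write_fasta(self, path) -> None:
        from .seqcore import write_fasta

        write_fasta(self.reads, path)

    def write_fastq(self, path, quality_char: str = "I") -> None:
        with open(path, "w") as fh:
            for name, seq in self.reads:
                fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


def generate_background(length: int, at_fraction: float, seed: int | np.random.Generator) -> str:
    """I.i.d. background sequence with the given A+T fraction.

    P(A)=P(T)=at/2 and P(C)=P(G)=(1-at)/2, emulating the AT-rich genomic
    background the satellite arrays sit in.
    """
    if not (0.0 <= at_fraction <= 1.0):
        raise ValueError("at_fraction must lie in [0, 1]")
    if length < 0:
        raise ValueError("length must be >= 0")
    if length == 0:
        return ""
    rng = _as_rng(seed)
    p = np.array(
        [at_fraction / 2, (1 - at_fraction) / 2, (1 - at_fraction) / 2, at_fraction / 2]
    )
    idx = rng.choice(4, size=length, p=p).astype(np.uint8)
    return _decode(idx)


def k2p_site_probabilities(divergence: float, kappa: float) -> tuple[float, float]:
    """Per-site transition (P) and transversion (Q) probabilities whose K2P
    distance expectation equals ``divergence`` at the given rate ratio.

    Under the K2P model with transition rate alpha and per-partner
    transversion rate beta, after branch length t:

        P = 1/4 + 1/4 exp(-4 beta t) - 1/2 exp(-2 (alpha+beta) t)
        Q = 1/2 - 1/2 exp(-4 beta t)

    and K = (alpha + 2 beta) t. Solving with kappa = alpha/beta gives
    beta t = K/(kappa+2), alpha t = kappa K/(kappa+2).
    """
    if divergence < 0 or divergence >= 0.75:
        raise ValueError("divergence must lie in [0, 0.75)")
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if divergence == 0:
        return 0.0, 0.0
    bt = divergence / (kappa + 2.0)
    at = kappa * bt
    P = 0.25 + 0.25 * math.exp(-4.0 * bt) - 0.5 * math.exp(-2.0 * (at + bt))
    Q = 0.5 - 0.5 * math.exp(-4.0 * bt)
    if P < 0 or Q < 0 or P + Q >= 1:
        raise ValueError(
            f"no valid (P,Q) for divergence={divergence}, kappa={kappa}"
        )
    return P, Q


def mutate_monomer(
    monomer: str,
    divergence: float,
    kappa: float = 2.0,
    indel_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> str:
    """One mutated copy of the consensus monomer.

    Each site is independently hit by a transition with probability P and a
    transversion with probability Q (Q/2 per partner), where (P, Q) solve
    the K2P forward model so the expected estimated K2P distance of the
    copy to the consensus equals ``divergence``. Indels (single-base, insert
    or delete with equal probability) occur at ``indel_rate`` per site.
    """
    rng = _as_rng(seed)
    P, Q = k2p_site_probabilities(divergence, kappa)
    idx = _encode(monomer).copy()
    n = idx.size
    if divergence > 0:
        u = rng.random(n)
        ts_mask = u < P
        tv_mask = (u >= P) & (u < P + Q)
        idx[ts_mask] = _TRANSITION[idx[ts_mask]]
        if tv_mask.any():
            partner = rng.integers(0, 2, size=int(tv_mask.sum()))
            idx[tv_mask] = _TRANSVERSION[idx[tv_mask], partner]
    if indel_rate > 0:
        u = rng.random(n)
        keep = u >= indel_rate / 2
        ins_mask = (u >= indel_rate / 2) & (u < indel_rate)
        pieces = []
        for i in range(n):
            if not keep[i]:
                continue
            pieces.append(idx[i : i + 1])
            if ins_mask[i]:
                pieces.append(rng.integers(0, 4, size=1).astype(np.uint8))
        idx = np.concatenate(pieces) if pieces else np.empty(0, dtype=np.uint8)
    return _decode(idx)


def _array_copy_counts(
    total_copies: int, n_arrays: int, cv: float, rng: np.random.Generator
) -> list[int]:
    """Split a copy budget over arrays with gamma-distributed relative sizes."""
    if n_arrays == 1:
        return [max(1, total_copies)]
    if cv <= 0:
        weights = np.ones(n_arrays)
    else:
        shape = 1.0 / (cv * cv)
        weights = rng.gamma(shape, 1.0 / shape, size=n_arrays)
        weights = np.clip(weights, 1e-9, None)
    counts = np.maximum(1, np.round(total_copies * weights / weights.sum()).astype(int))
    # steer the total back onto the budget by adjusting the largest array
    diff = total_copies - int(counts.sum())
    j = int(np.argmax(counts))
    counts[j] = max(1, counts[j] + diff)
    return counts.tolist()


def build_genome(spec: SimSpec) -> tuple[list[tuple[str, str]], TruthTable]:
    """Assemble one synthetic genome and its ground-truth table.

    For each family, ``n_arrays`` tandem arrays of independently mutated
    monomer copies are placed in random order, separated by at least
    ``2 * read_length`` of background so no read can bridge two arrays.
    Total family bp lands within 1% of ``target_proportion * genome_length``
    (monomer granularity permitting).
    """
    rng = _as_rng(spec.seed)
    G = spec.genome_length
    contig_id = "chr1"

    arrays: list[tuple[str, str, float]] = []  # (family, sequence, realized divergence)
    for fam in spec.families:
        target_bp = fam.target_proportion * G
        m = len(fam.monomer)
        total_copies = max(fam.n_arrays, int(round(target_bp / m)))
        counts = _array_copy_counts(total_copies, fam.n_arrays, fam.array_length_cv, rng)
        consensus_idx = _encode(fam.monomer)
        for c in counts:
            copies = []
            div_sum = 0.0
            for _ in range(c):
                copy = mutate_monomer(
                    fam.monomer, fam.divergence, fam.kappa, fam.indel_rate, rng
                )
                if len(copy) == m:
                    div_sum += float((_encode(copy) != consensus_idx).mean())
                copies.append(copy)
            arrays.append((fam.name, "".join(copies), div_sum / c if c else 0.0))

    sat_bp = sum(len(seq) for _, seq, _ in arrays)
    n_gaps = len(arrays) + 1
    min_gap = 2 * spec.read_length
    bg_bp = G - sat_bp
    if bg_bp < n_gaps * min_gap:
        raise ValueError(
            "array packing infeasible: background too small for the required "
            "inter-array spacing; lower the family proportions or array counts"
        )

    order = rng.permutation(len(arrays))
    # split the spare background over the gaps (multinomial, uniform weights)
    spare = bg_bp - n_gaps * min_gap
    gap_extra = rng.multinomial(spare, np.full(n_gaps, 1.0 / n_gaps))
    background = generate_background(bg_bp, spec.background_at, rng)

    pieces: list[str] = []
    pos = 0
    bg_used = 0
    placed: dict[str, list[tuple[str, int, int]]] = {f.name: [] for f in spec.families}
    div_acc: dict[str, list[float]] = {f.name: [] for f in spec.families}
    bp_acc: dict[str, int] = {f.name: 0 for f in spec.families}
    for gi, ai in enumerate(order):
        gap_len = min_gap + int(gap_extra[gi])
        pieces.append(background[bg_used : bg_used + gap_len])
        bg_used += gap_len
        pos += gap_len
        fam_name, seq, rdiv = arrays[ai]
        placed[fam_name].append((contig_id, pos, pos + len(seq)))
        div_acc[fam_name].append(rdiv)
        bp_acc[fam_name] += len(seq)
        pieces.append(seq)
        pos += len(seq)
    pieces.append(background[bg_used:])
    genome = "".join(pieces)
    assert len(genome) == G

    rows = {}
    for fam in spec.families:
        divs = div_acc[fam.name]
        rows[fam.name] = TruthRow(
            name=fam.name,
            true_bp=bp_acc[fam.name],
            true_proportion=bp_acc[fam.name] / G,
            realized_divergence=float(np.mean(divs)) if divs else 0.0,
            intervals=sorted(placed[fam.name], key=lambda t: t[1]),
        )
    return [(contig_id, genome)], TruthTable(genome_length=G, rows=rows)


def shear_reads(
    genome: str | Sequence[tuple[str, str]],
    read_length: int,
    coverage: float,
    seed: int | np.random.Generator,
) -> ReadSet:
    """Uniform single-end shearing of a genome to a target fold coverage.

    N_reads = round(coverage * genome_length / read_length); start positions
    uniform, strands equiprobable.
    """
    if not isinstance(genome, str):
        if len(genome) != 1:
            raise ValueError("shear_reads expects a single-contig genome")
        genome = genome[0][1]
    G = len(genome)
    if read_length > G:
        raise ValueError("read_length exceeds genome length")
    rng = _as_rng(seed)
    n_reads = int(round(coverage * G / read_length))
    starts = rng.integers(0, G - read_length + 1, size=n_reads)
    strands = rng.integers(0, 2, size=n_reads)
    reads = []
    for i in range(n_reads):
        s = int(starts[i])
        seq = genome[s : s + read_length]
        strand = "+" if strands[i] == 0 else "-"
        if strand == "-":
            seq = reverse_complement(seq)
        reads.append((f"read{i:07d}|{s}|{strand}", seq))
    return ReadSet(reads=reads, total_bp=n_reads * read_length, read_length=read_length)


def simulate_species_set(
    base_spec: SimSpec,
    perturbations: Mapping[str, Mapping[str, tuple[float, float]]],
    seed: int | np.random.Generator,
) -> list[tuple[str, ReadSet, TruthTable]]:
    """Simulate several "species" sharing one monomer pool (library hypothesis).

    ``perturbations`` maps species label -> {family name: (abundance
    multiplier, divergence offset)}. A multiplier of 0 removes the family
    from that species; unlisted families keep the base parameters. Each
    species gets an independently generated genome and read set, all derived
    from ``seed``.
    """
    ss = np.random.SeedSequence(
        seed if isinstance(seed, int) else int(_as_rng(seed).integers(2**31))
    )
    children = ss.spawn(len(perturbations))
    out = []
    for (label, pert), child in zip(perturbations.items(), children):
        families = []
        for fam in base_spec.families:
            mult, doff = pert.get(fam.name, (1.0, 0.0))
            if mult < 0:
                raise ValueError("abundance multipliers must be >= 0")
            if mult == 0:
                continue
            families.append(
                FamilySimSpec(
                    monomer=fam.monomer,
                    target_proportion=fam.target_proportion * mult,
                    divergence=fam.divergence + doff,
                    kappa=fam.kappa,
                    n_arrays=fam.n_arrays,
                    array_length_cv=fam.array_length_cv,
                    indel_rate=fam.indel_rate,
                    name=fam.name,
                )
            )
        child_seed = int(child.generate_state(1)[0] % (2**31))
        spec = SimSpec(
            genome_length=base_spec.genome_length,
            families=families,
            background_at=base_spec.background_at,
            read_length=base_spec.read_length,
            coverage=base_spec.coverage,
            seed=child_seed,
        )
        genome, truth = build_genome(spec)
        reads = shear_reads(genome, spec.read_length, spec.coverage, child_seed + 1)
        # families removed by a zero multiplier still get a truth row
        for fam in base_spec.families:
            if fam.name not in truth.rows:
                truth.rows[fam.name] = TruthRow(fam.name, 0, 0.0, 0.0, [])
        out.append((label, reads, truth))
    return out
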