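"""Read-to-consensus alignment and Kimura 2-parameter divergence.

Reads (or assembly windows) are aligned to dimer/concatemer references of
each satellite family with a seed-and-extend strategy: exact k-mer seeds
nominate (read, family, strand) candidates, which are then aligned with an
affine-gap Smith-Waterman. Each alignment yields transition/transversion
counts and a K2P divergence; per-read overlapping hits are resolved to the
highest-scoring family so abundances sum correctly.

The K2P distance corrects observed transition (P) and transversion (Q)
proportions for multiple hits:

    K = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from numba import njit

from .seqcore import SatLibrary, build_reference, reverse_complement

__all__ = [
    "AlignmentRecord",
    "MaskResult",
    "MaskParams",
    "Scoring",
    "SaturatedDivergenceError",
    "k2p_distance",
    "count_substitutions",
    "local_align",
    "mask_sample",
    "mask_assembly",
    "write_mask_tsv",
    "read_mask_tsv",
    "read_repeatmasker_align",
]

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class SaturatedDivergenceError(ValueError):
    """K2P log argument non-positive: divergence beyond the model's reach."""


def k2p_distance(P: float, Q: float) -> float:
    """Kimura 2-parameter distance from transition/transversion proportions.

    Returns a fraction; callers scale to percent. Raises
    :class:`SaturatedDivergenceError` outside the log domain
    (1 - 2P - Q <= 0 or 1 - 2Q <= 0).
    """
    if P < 0 or Q < 0:
        raise ValueError("P and Q must be non-negative")
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturatedDivergenceError(
            f"saturated divergence: P={P:.4f}, Q={Q:.4f} outside the K2P domain"
        )
    return -0.5 * math.log(w1 * math.sqrt(w2))


def count_substitutions(aligned_read: str, aligned_ref: str) -> tuple[int, int, int, int]:
    """Classify columns of a gapped alignment pair.

    Returns (transitions, transversions, aligned_columns, gap_columns).
    Transitions are A<->G and C<->T. Gap columns are excluded from
    aligned_columns; columns carrying an ambiguity code are excluded from
    every count.
    """
    if len(aligned_read) != len(aligned_ref):
        raise ValueError("gapped strings must have equal length")
    ts = tv = aligned = gaps = 0
    for x, y in zip(aligned_read.upper(), aligned_ref.upper()):
        if x == "-" or y == "-":
            gaps += 1
            continue
        if x not in "ACGT" or y not in "ACGT":
            continue
        aligned += 1
        if x != y:
            if (x, y) in _TRANSITIONS:
                ts += 1
            else:
                tv += 1
    return ts, tv, aligned, gaps


@dataclass(frozen=True)
class Scoring:
    """Affine-gap local alignment scores; a gap of length k costs
    ``gap_open + (k - 1) * gap_extend``."""

    match: int = 1
    mismatch: int = -1
    gap_open: int = -4
    gap_extend: int = -1


@dataclass
class Alignment:
    """A local alignment of a read against a reference."""

    aligned_read: str
    aligned_ref: str
    score: int
    read_span: tuple[int, int]  # 0-based half-open on the read
    ref_span: tuple[int, int]  # 0-based half-open on the reference


@dataclass
class AlignmentRecord:
    """One read(region)-to-family alignment with substitution accounting."""

    read_id: str
    family: str
    strand: str
    read_start: int
    read_end: int
    ref_start: int
    ref_end: int
    aligned_columns: int
    transitions: int
    transversions: int
    gap_columns: int
    k2p_divergence: float  # percent
    score: int
    read_length: int
    bp_weight: int = 0  # read-span bp credited to abundance (assembly dedup may clip)

    def __post_init__(self) -> None:
        if self.bp_weight == 0:
            self.bp_weight = self.read_end - self.read_start

    @property
    def read_span_bp(self) -> int:
        return self.read_end - self.read_start


@dataclass
class MaskResult:
    """All alignments of one sample against one family library."""

    sample: str
    total_sampled_bp: int
    records: list[AlignmentRecord]
    n_reads: int = 0

    def by_family(self, family: str) -> list[AlignmentRecord]:
        return [r for r in self.records if r.family == family]

    @property
    def families(self) -> list[str]:
        seen = []
        for r in self.records:
            if r.family not in seen:
                seen.append(r.family)
        return seen


@dataclass(frozen=True)
class MaskParams:
    """Seed-and-extend parameters (all tunable from the CLI)."""

    k_seed: int = 12
    min_score: int = 18
    min_aligned: int = 30
    scoring: Scoring = field(default_factory=Scoring)


_GAP_CODE = 9


@njit(cache=True)
def _sw_align(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    """Affine Smith-Waterman with deterministic traceback.

    a, b are int8 arrays (0..3 bases, 4 ambiguous). On ties the traceback
    prefers diagonal, then up (gap in reference), then left (gap in read).
    Returns score, spans and gapped sequences (code 9 = gap).
    """
    n = a.shape[0]
    m = b.shape[0]
    NEG = -10**9
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int32)  # gap in read (left)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int32)  # gap in ref (up)
    ptrH = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 stop, 1 diag, 2 up, 3 left
    ptrE = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 open, 1 extend
    ptrF = np.zeros((n + 1, m + 1), dtype=np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            e_open = H[i, j - 1] + gap_open
            e_ext = E[i, j - 1] + gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                ptrE[i, j] = 0
            else:
                E[i, j] = e_ext
                ptrE[i, j] = 1
            f_open = H[i - 1, j] + gap_open
            f_ext = F[i - 1, j] + gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                ptrF[i, j] = 0
            else:
                F[i, j] = f_ext
                ptrF[i, j] = 1
            if ai < 4 and ai == b[j - 1]:
                s = match
            else:
                s = mismatch
            diag = H[i - 1, j - 1] + s
            h = 0
            p = 0
            if diag >= h:
                h = diag
                p = 1
            if F[i, j] > h:
                h = F[i, j]
                p = 2
            if E[i, j] > h:
                h = E[i, j]
                p = 3
            if h <= 0:
                h = 0
                p = 0
            H[i, j] = h
            ptrH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback
    cap = n + m
    ar = np.empty(cap, dtype=np.int8)
    br = np.empty(cap, dtype=np.int8)
    k = 0
    i = bi
    j = bj
    state = 0  # 0 = H, 1 = F(up), 2 = E(left)
    while i > 0 or j > 0:
        if state == 0:
            p = ptrH[i, j]
            if p == 0:
                break
            if p == 1:
                ar[k] = a[i - 1]
                br[k] = b[j - 1]
                k += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            ar[k] = a[i - 1]
            br[k] = _GAP_CODE
            k += 1
            if ptrF[i, j] == 0:
                state = 0
            i -= 1
        else:
            ar[k] = _GAP_CODE
            br[k] = b[j - 1]
            k += 1
            if ptrE[i, j] == 0:
                state = 0
            j -= 1
    return best, i, bi, j, bj, ar[:k][::-1].copy(), br[:k][::-1].copy()


_ENC = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
    _ENC[_b + 32] = _i

_DEC = {0: "A", 1: "C", 2: "G", 3: "T", 4: "N", _GAP_CODE: "-"}


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _decode_gapped(codes: np.ndarray) -> str:
    return "".join(_DEC[int(c)] for c in codes)


def local_align(read: str, reference: str, scoring: Scoring = Scoring()) -> Alignment:
    """Optimal affine-gap Smith-Waterman local alignment.

    Deterministic: the maximal cell is the first one reached in row-major
    order, and traceback prefers diagonal over up over left on score ties.
    """
    if not read or not reference:
        raise ValueError("sequences must be non-empty")
    a = _encode(read)
    b = _encode(reference)
    score, ri, re_, ci, ce = 0, 0, 0, 0, 0
    score, ri, re_, ci, ce, ar, br = _sw_align(
        a, b, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    )
    return Alignment(
        aligned_read=_decode_gapped(ar),
        aligned_ref=_decode_gapped(br),
        score=int(score),
        read_span=(int(ri), int(re_)),
        ref_span=(int(ci), int(ce)),
    )


def _reference_map(library: SatLibrary, target_len: int = 200) -> dict[str, str]:
    return {fam.name: build_reference(fam.monomer, target_len) for fam in library}


def _kmer_index(refs: dict[str, str], ranks: dict[str, int], k: int):
    """Exact k-mer -> list of (family, strand) over both strands of each reference."""
    index: dict[str, set[tuple[str, str]]] = {}
    for name, ref in refs.items():
        for strand, seq in (("+", ref), ("-", reverse_complement(ref))):
            for i in range(len(seq) - k + 1):
                index.setdefault(seq[i : i + k], set()).add((name, strand))
    return index


def _make_record(
    read_id: str,
    read_len: int,
    family: str,
    strand: str,
    aln: Alignment,
    ref_len: int,
) -> AlignmentRecord | None:
    ts, tv, aligned, gaps = count_substitutions(aln.aligned_read, aln.aligned_ref)
    if aligned == 0:
        return None
    try:
        k2p = 100.0 * k2p_distance(ts / aligned, tv / aligned)
    except SaturatedDivergenceError:
        return None  # junk alignment beyond the model's reach; do not credit
    rs, re_ = aln.ref_span
    if strand == "-":
        rs, re_ = ref_len - re_, ref_len - rs
    return AlignmentRecord(
        read_id=read_id,
        family=family,
        strand=strand,
        read_start=aln.read_span[0],
        read_end=aln.read_span[1],
        ref_start=rs,
        ref_end=re_,
        aligned_columns=aligned,
        transitions=ts,
        transversions=tv,
        gap_columns=gaps,
        k2p_divergence=k2p,
        score=aln.score,
        read_length=read_len,
    )


def mask_sample(
    reads: Iterable[tuple[str, str]],
    library: SatLibrary,
    params: MaskParams = MaskParams(),
    sample: str = "sample",
    total_sampled_bp: int | None = None,
) -> MaskResult:
    """Align reads to the dimer/concatemer library (seed-and-extend).

    A (read, family, strand) pair is aligned only when the read shares at
    least one exact ``k_seed``-mer with that strand of the family reference.
    Per read, overlapping hits are resolved to the highest-scoring family
    (ties: lower family rank); records under ``min_score`` or with fewer
    than ``min_aligned`` aligned columns are dropped.
    """
    if len(library) == 0:
        raise ValueError("empty library")
    refs = _reference_map(library)
    ranks = {fam.name: fam.rank for fam in library}
    k = params.k_seed
    index = _kmer_index(refs, ranks, k)
    refs_minus = {name: reverse_complement(ref) for name, ref in refs.items()}

    records: list[AlignmentRecord] = []
    total_bp = 0
    n_reads = 0
    for read_id, seq in reads:
        n_reads += 1
        total_bp += len(seq)
        seq = seq.upper()
        candidates: set[tuple[str, str]] = set()
        for i in range(len(seq) - k + 1):
            hit = index.get(seq[i : i + k])
            if hit:
                candidates.update(hit)
        if not candidates:
            continue
        # iterated best-hit extraction: accept the highest-scoring hit
        # (ties: lower family rank), mask its span, re-align the remainder —
        # so a long window tiles into several non-overlapping records
        work = seq
        cand_list = sorted(candidates)
        while True:
            hits = []
            for family, strand in cand_list:
                ref = refs[family] if strand == "+" else refs_minus[family]
                aln = local_align(work, ref, params.scoring)
                if aln.score < params.min_score:
                    continue
                rec = _make_record(read_id, len(seq), family, strand, aln, len(ref))
                if rec is None or rec.aligned_columns < params.min_aligned:
                    continue
                hits.append(rec)
            if not hits:
                break
            hits.sort(key=lambda r: (-r.score, ranks[r.family], r.family, r.strand))
            best = hits[0]
            records.append(best)
            work = (
                work[: best.read_start]
                + "N" * (best.read_end - best.read_start)
                + work[best.read_end :]
            )
    if total_sampled_bp is None:
        total_sampled_bp = total_bp
    return MaskResult(
        sample=sample, total_sampled_bp=total_sampled_bp, records=records, n_reads=n_reads
    )


def mask_assembly(
    assembly: Sequence[tuple[str, str]],
    library: SatLibrary,
    params: MaskParams = MaskParams(),
    window: int = 1000,
    overlap: int = 150,
    sample: str = "assembly",
) -> MaskResult:
    """Mask an assembly by cutting it into overlapping windows treated as reads.

    Hits overlapping in genomic coordinates (same family) are deduplicated
    before abundance computation by clipping each record's credited bp to
    the not-yet-covered part of the genome; the abundance denominator is the
    total assembly length.
    """
    if overlap >= window:
        raise ValueError("overlap must be smaller than window")
    step = window - overlap
    windows = []
    total_bp = 0
    for contig_id, seq in assembly:
        total_bp += len(seq)
        if not seq:
            continue
        for start in range(0, max(1, len(seq) - overlap), step):
            chunk = seq[start : start + window]
            if len(chunk) < params.min_aligned:
                continue
            windows.append((f"{contig_id}|{start}", chunk))
    result = mask_sample(windows, library, params, sample=sample, total_sampled_bp=total_bp)
    # deduplicate by genomic coordinate, per family
    genomic = []
    for rec in result.records:
        contig, off = rec.read_id.rsplit("|", 1)
        off = int(off)
        genomic.append((rec.family, contig, off + rec.read_start, off + rec.read_end, rec))
    genomic.sort(key=lambda t: (t[0], t[1], t[2], t[3]))
    deduped: list[AlignmentRecord] = []
    cov_end: dict[tuple[str, str], int] = {}
    for family, contig, gs, ge, rec in genomic:
        key = (family, contig)
        covered_to = cov_end.get(key, -1)
        eff_start = max(gs, covered_to)
        if eff_start >= ge:
            continue  # fully inside already-credited territory
        rec = replace(rec, bp_weight=ge - eff_start)
        cov_end[key] = ge
        deduped.append(rec)
    result.records = deduped
    return result


# ---------------------------------------------------------------------------
# serialization: RepeatMasker-.out-like TSV with a K2P column
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "score",
    "k2p_pct",
    "read_id",
    "read_begin",
    "read_end",
    "strand",
    "family",
    "ref_begin",
    "ref_end",
    "aligned_cols",
    "transitions",
    "transversions",
    "gap_cols",
    "read_length",
    "bp_weight",
]


def write_mask_tsv(result: MaskResult, path: str | Path) -> None:
    """Write alignments as TSV (1-based inclusive coordinates, strand +/C)."""
    with open(path, "w") as fh:
        fh.write(f"# sample={result.sample}\n")
        fh.write(f"# total_sampled_bp={result.total_sampled_bp}\n")
        fh.write(f"# n_reads={result.n_reads}\n")
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for r in result.records:
            strand = "+" if r.strand == "+" else "C"
            fh.write(
                f"{r.score}\t{r.k2p_divergence:.4f}\t{r.read_id}\t"
                f"{r.read_start + 1}\t{r.read_end}\t{strand}\t{r.family}\t"
                f"{r.ref_start + 1}\t{r.ref_end}\t{r.aligned_columns}\t"
                f"{r.transitions}\t{r.transversions}\t{r.gap_columns}\t"
                f"{r.read_length}\t{r.bp_weight}\n"
            )


def read_mask_tsv(path: str | Path) -> MaskResult:
    sample, total_bp, n_reads = "sample", 0, 0
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                if key == "sample":
                    sample = val
                elif key == "total_sampled_bp":
                    total_bp = int(val)
                elif key == "n_reads":
                    n_reads = int(val)
                continue
            if not line or line.startswith("score\t"):
                continue
            p = line.split("\t")
            records.append(
                AlignmentRecord(
                    read_id=p[2],
                    family=p[6],
                    strand="+" if p[5] == "+" else "-",
                    read_start=int(p[3]) - 1,
                    read_end=int(p[4]),
                    ref_start=int(p[7]) - 1,
                    ref_end=int(p[8]),
                    aligned_columns=int(p[9]),
                    transitions=int(p[10]),
                    transversions=int(p[11]),
                    gap_columns=int(p[12]),
                    k2p_divergence=float(p[1]),
                    score=int(p[0]),
                    read_length=int(p[13]),
                    bp_weight=int(p[14]),
                )
            )
    return MaskResult(sample=sample, total_sampled_bp=total_bp, records=records, n_reads=n_reads)


_ALIGN_HEADER = re.compile(
    r"^\s*(\d+)\s+([\d.]+)\s+([\d.]+)\s+([\d.]+)\s+(\S+)\s+(\d+)\s+(\d+)\s+\((\d+)\)\s+"
    r"(C\s+)?(\S+?)(?:#\S+)?\s+"
)
_KIMURA_LINE = re.compile(r"^Kimura.*=\s*([\d.]+)")


def read_repeatmasker_align(
    path: str | Path, total_sampled_bp: int, sample: str = "sample"
) -> MaskResult:
    """Read a genuine RepeatMasker ``.align`` file (post-processed with the
    Kimura-divergence script, so each block carries a ``Kimura ... = x`` line).

    Only the per-hit header and Kimura lines are used: enough to feed the
    abundance, landscape and TSI statistics. Substitution counts are not
    recoverable from headers and are left at zero.
    """
    records: list[AlignmentRecord] = []
    pending = None
    with open(path) as fh:
        for line in fh:
            m = _ALIGN_HEADER.match(line)
            if m:
                if pending is not None:
                    records.append(pending)
                score = int(m.group(1))
                div_pct = float(m.group(2))
                qname = m.group(5)
                qbeg, qend, qleft = int(m.group(6)), int(m.group(7)), int(m.group(8))
                strand = "-" if m.group(9) else "+"
                family = m.group(10)
                pending = AlignmentRecord(
                    read_id=qname,
                    family=family,
                    strand=strand,
                    read_start=qbeg - 1,
                    read_end=qend,
                    ref_start=0,
                    ref_end=0,
                    aligned_columns=qend - qbeg + 1,
                    transitions=0,
                    transversions=0,
                    gap_columns=0,
                    k2p_divergence=div_pct,
                    score=score,
                    read_length=qend + qleft,
                )
                continue
            k = _KIMURA_LINE.match(line)
            if k and pending is not None:
                pending.k2p_divergence = float(k.group(1))
    if pending is not None:
        records.append(pending)
    read_ids = {r.read_id for r in records}
    return MaskResult(
        sample=sample,
        total_sampled_bp=total_sampled_bp,
        records=records,
        n_reads=len(read_ids),
    )
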