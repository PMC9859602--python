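"""Cross-sample satellitome comparison.

Abundance and divergence of a shared family library measured in several
read samples, expressed as log2 abundance ratios against a reference
sample, presence/absence calls, and the rank and paired statistics used to
compare satellitomes: Spearman's rank correlation and the exact Wilcoxon
signed-rank test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .repeat_align import MaskResult
from .satstats import genome_proportion

__all__ = [
    "ComparativeResult",
    "log2_ratio",
    "classify_abundance_change",
    "presence_call",
    "spearman_rho",
    "wilcoxon_signed_rank_exact",
    "compare_samples",
]

#: Invented presence criterion (the source study never defines one):
#: a family is present when it reaches both thresholds.
MIN_PRESENCE_ABUNDANCE = 1e-4  # percent of sampled bp
MIN_PRESENCE_READS = 10


def log2_ratio(sample_abundance: float, reference_abundance: float) -> float:
    """log2 of sample/reference abundance; both must be positive."""
    if sample_abundance <= 0 or reference_abundance <= 0:
        raise ValueError("log2 ratio undefined for zero/absent abundance")
    return math.log2(sample_abundance / reference_abundance)


def classify_abundance_change(ratio: float, threshold: float = 0.6) -> str:
    """Classify a log2 abundance ratio: lower (< -t), higher (> +t), else similar.

    Inequalities are strict: a ratio of exactly +/-threshold is "similar".
    """
    if ratio < -threshold:
        return "lower"
    if ratio > threshold:
        return "higher"
    return "similar"


def presence_call(
    abundance_pct: float,
    n_reads: int,
    min_abundance: float = MIN_PRESENCE_ABUNDANCE,
    min_reads: int = MIN_PRESENCE_READS,
) -> bool:
    return abundance_pct >= min_abundance and n_reads >= min_reads


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman's rank correlation with mean ranks for ties; p from the
    t approximation. Raises on constant input (undefined correlation)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def _signed_rank_distribution(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of W+ = sum of ranks carrying a positive sign,
    over all 2^n equiprobable sign assignments.

    Average ranks of tied magnitudes may be half-integers, so the dynamic
    program runs on doubled ranks. Returns (support of 2*W+, probabilities).
    """
    doubled = np.round(2 * ranks).astype(int)
    total = int(doubled.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: dist.size - r]
        dist = 0.5 * (dist + shifted)
    return np.arange(total + 1), dist


def wilcoxon_signed_rank_exact(
    x: Sequence[float], y: Sequence[float]
) -> float:
    """Exact two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped (p = 1 by convention when none remain);
    tied absolute differences receive average ranks. The p-value is
    ``min(1, 2 * min(P(W+ <= w), P(W+ >= w)))`` under the exact null
    distribution of the positive-rank sum W+, equivalent to full
    enumeration of all sign assignments.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    ranks = sps.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    support, dist = _signed_rank_distribution(ranks)
    w2 = int(round(2 * w))
    p_le = float(dist[support <= w2].sum())
    p_ge = float(dist[support >= w2].sum())
    return min(1.0, 2.0 * min(p_le, p_ge))


@dataclass
class ComparativeResult:
    """Per-(family, sample) abundance/divergence with reference-relative ratios."""

    reference: str
    samples: list[str]
    table: pd.DataFrame  # columns: family, sample, abundance, mean_k2p, n_reads,
    #          presence, log2_ratio, change

    def per_sample_summary(self) -> pd.DataFrame:
        present = self.table[self.table.presence]
        return present.groupby("sample").agg(
            n_families=("family", "nunique"), total_pct=("abundance", "sum")
        )

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def compare_samples(
    mask_results: Sequence[MaskResult],
    reference: str,
    library,
    min_abundance: float = MIN_PRESENCE_ABUNDANCE,
    min_reads: int = MIN_PRESENCE_READS,
    change_threshold: float = 0.6,
) -> ComparativeResult:
    """Assemble the cross-sample comparison table.

    All samples must have been masked with the same library. Families are
    ordered by library rank; a family absent from a sample appears with
    presence False and no numeric log2 ratio. Abundances are already
    normalized percentages, so differing sample sizes need no rescaling.
    """
    labels = [m.sample for m in mask_results]
    if reference not in labels:
        raise ValueError(f"reference sample {reference!r} not among {labels}")
    by_label: Mapping[str, MaskResult] = {m.sample: m for m in mask_results}
    ref_mask = by_label[reference]

    rows = []
    for fam in library:
        ref_abund = genome_proportion(ref_mask, fam.name)
        ref_reads = len({r.read_id for r in ref_mask.by_family(fam.name)})
        ref_present = presence_call(ref_abund, ref_reads, min_abundance, min_reads)
        for label in labels:
            mask = by_label[label]
            recs = mask.by_family(fam.name)
            abund = genome_proportion(mask, fam.name)
            n_reads = len({r.read_id for r in recs})
            w = sum(r.bp_weight for r in recs)
            mean_k2p = (
                sum(r.k2p_divergence * r.bp_weight for r in recs) / w if w else None
            )
            present = presence_call(abund, n_reads, min_abundance, min_reads)
            if present and ref_present:
                ratio = log2_ratio(abund, ref_abund)
                change = classify_abundance_change(ratio, change_threshold)
            else:
                ratio, change = None, "absent"
            rows.append(
                {
                    "family": fam.name,
                    "sample": label,
                    "abundance": abund,
                    "mean_k2p": mean_k2p,
                    "n_reads": n_reads,
                    "presence": present,
                    "log2_ratio": ratio,
                    "change": change,
                }
            )
    return ComparativeResult(
        reference=reference, samples=labels, table=pd.DataFrame(rows)
    )
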