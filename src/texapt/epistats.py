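"""Companion statistics: subfamily-normalized methylation and DNase levels,
and dual-luciferase reporter analysis.

The normalization shared by the methylation and DNase analyses divides the
tag count in a candidate TE's binding-site footprint by the tag count over
the homologous (consensus-projected) footprint across all copies of the
subfamily, cancelling library-size differences. Hypomethylation in tumours
is assessed with a one-sample lower-tail t-test on paired tumour-normal
differences; differential DNase sensitivity with a one-tailed two-sample
proportion test (Yates-corrected chi-square); luciferase TE-deletion effects
with a lower-tail pooled-variance two-sample t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .intervals import GenomicInterval, TECopy
from .metaprofile import TagTrack


@dataclass(frozen=True)
class RegionCounts:
    """Tag counts for one sample: candidate-footprint vs whole-subfamily footprint."""

    sample_id: str
    condition: str
    candidate_count: int
    subfamily_count: int

    def __post_init__(self) -> None:
        if self.candidate_count < 0 or self.subfamily_count < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    tail: str  # "lower" or "upper"
    p_value: float
    test_name: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


@dataclass(frozen=True)
class LuciferasePlate:
    """Triplicate firefly/Renilla luminescence for one construct in one experiment."""

    construct: str  # wild-type / TE-deleted / positive control label
    firefly: tuple[float, float, float]
    renilla: tuple[float, float, float]
    experiment: int

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.firefly + self.renilla):
            raise ValueError("luminescence values must be > 0")


# ---------------------------------------------------------------------------
# consensus-coordinate projection
# ---------------------------------------------------------------------------

def _consensus_pos(copy: TECopy, g: int) -> int:
    """Consensus position (1-based) of genomic base ``g`` within ``copy``.

    Affine floor map: offsets along the copy scale linearly onto the
    consensus span; minus-strand copies run antiparallel (genomic leftmost
    base maps to rep_end).
    """
    iv = copy.interval
    G = len(iv)
    C = copy.rep_end - copy.rep_start + 1
    o = (g - iv.start) * C // G
    if iv.strand == "-":
        return copy.rep_end - o
    return copy.rep_start + o


def homologous_regions(
    candidate_te: TECopy,
    tfbs: GenomicInterval,
    subfamily_copies: Sequence[TECopy],
) -> list[GenomicInterval]:
    """Project the TFBS footprint onto consensus coordinates and lift it into
    every subfamily copy whose consensus span covers >= 1 bp of it.

    The genomic<->consensus map is affine with integer floor; the lift is the
    exact preimage of the consensus footprint under each copy's map, so the
    operation is idempotent and lifted intervals never exceed their host copy.
    """
    if candidate_te.interval.chrom != tfbs.chrom or not (
        tfbs.start < candidate_te.interval.end
        and tfbs.end > candidate_te.interval.start
    ):
        raise ValueError("TFBS does not overlap the candidate TE")
    # clip footprint to the candidate copy, then project its end bases
    g0 = max(tfbs.start, candidate_te.interval.start)
    g1 = min(tfbs.end, candidate_te.interval.end) - 1  # inclusive
    c_a = _consensus_pos(candidate_te, g0)
    c_b = _consensus_pos(candidate_te, g1)
    a, b = min(c_a, c_b), max(c_a, c_b)

    out: list[GenomicInterval] = []
    for copy in subfamily_copies:
        lo = max(a, copy.rep_start)
        hi = min(b, copy.rep_end)
        if lo > hi:
            continue
        iv = copy.interval
        G = len(iv)
        C = copy.rep_end - copy.rep_start + 1
        if iv.strand == "-":
            # o in [rep_end - hi, rep_end - lo] on the offset scale
            o_lo, o_hi = copy.rep_end - hi, copy.rep_end - lo
        else:
            o_lo, o_hi = lo - copy.rep_start, hi - copy.rep_start
        # preimage of floor(o*C/G) in [o_lo, o_hi]:
        g_lo = iv.start + math.ceil(o_lo * G / C)
        g_hi = iv.start + math.ceil((o_hi + 1) * G / C) - 1
        g_lo = max(g_lo, iv.start)
        g_hi = min(g_hi, iv.end - 1)
        if g_lo > g_hi:
            continue
        out.append(
            GenomicInterval(iv.chrom, g_lo, g_hi + 1, iv.strand,
                            name=copy.te_subfamily)
        )
    return out


def normalized_level(
    candidate_regions: Sequence[GenomicInterval],
    subfamily_regions: Sequence[GenomicInterval],
    track: TagTrack,
) -> float:
    """Distinct tags in the candidate footprint / distinct tags in the
    subfamily-wide footprint; raises when the denominator is zero."""
    def _count(regions: Sequence[GenomicInterval]) -> int:
        hit: set[tuple] = set()
        for r in regions:
            s, e = track.query(r.chrom, r.start, r.end)
            hit.update(zip([r.chrom] * len(s), s.tolist(), e.tolist()))
        return len(hit)

    denom = _count(subfamily_regions)
    if denom == 0:
        raise ValueError("no tags in the subfamily footprint; level undefined")
    return _count(candidate_regions) / denom


# ---------------------------------------------------------------------------
# the three tests
# ---------------------------------------------------------------------------

def paired_methylation_test(pairs: Sequence[tuple[float, float]]) -> TestResult:
    """One-sample lower-tail t-test on tumour-minus-normal level differences.

    H1: mean difference < 0 (hypomethylation in tumours).
    """
    if len(pairs) < 2:
        raise ValueError("need >= 2 pairs")
    d = np.array([t - n for t, n in pairs], dtype=float)
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero variance of paired differences; test degenerate")
    n = d.size
    t_stat = d.mean() / (sd / math.sqrt(n))
    p = float(stats.t.cdf(t_stat, df=n - 1))
    return TestResult(t_stat, n - 1, "lower", p, "paired one-sample t (lower tail)")


def dnase_proportion_test(
    x1: int, n1: int, x2: int, n2: int,
    direction: str = "greater",
    yates: bool = True,
) -> TestResult:
    """One-tailed two-sample proportion test via a (optionally Yates-corrected)
    chi-square on the 2x2 table [[x1, n1-x1], [x2, n2-x2]].

    One-tailed p is half the chi-square upper tail when the observed direction
    matches ``direction`` (sample 1 vs sample 2), else one minus that half.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0:
            raise ValueError("sample sizes must be > 0")
        if not 0 <= x <= n:
            raise ValueError("counts must satisfy 0 <= x <= n")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        chi2 = 0.0
    else:
        chi2, _, _, _ = stats.chi2_contingency(table, correction=yates)
    p_two = float(stats.chi2.sf(chi2, df=1))
    delta = x1 / n1 - x2 / n2
    matches = (delta > 0) if direction == "greater" else (delta < 0)
    if chi2 == 0.0 or delta == 0.0:
        p = 0.5 if p_two >= 1.0 else p_two / 2  # null centre
    elif matches:
        p = p_two / 2
    else:
        p = 1.0 - p_two / 2
    tail = "upper" if direction == "greater" else "lower"
    return TestResult(float(chi2), 1, tail, p, "two-sample proportion (chi-square, one-tailed)")


def one_tailed_p_from_chi2(chi2: float) -> float:
    """One-tailed p for a df=1 proportion-test chi-square whose observed
    direction matches the alternative: half the upper-tail probability."""
    return float(stats.chi2.sf(chi2, df=1)) / 2


def luciferase_relative_activity(
    plates: Sequence[LuciferasePlate],
    positive_control: str = "positive control",
) -> dict[str, float]:
    """Per-construct relative activity within one experiment.

    Per well firefly:Renilla ratio -> triplicate mean per construct -> divided
    by the positive-control construct mean.
    """
    means: dict[str, float] = {}
    for p in plates:
        ratios = [f / r for f, r in zip(p.firefly, p.renilla)]
        means[p.construct] = float(np.mean(ratios))
    if positive_control not in means:
        raise ValueError(f"positive control construct {positive_control!r} missing")
    ref = means[positive_control]
    return {c: m / ref for c, m in means.items()}


def normalize_to_wildtype(
    per_experiment: Sequence[Mapping[str, float]],
    wildtype: str = "wild-type",
) -> dict[str, list[float]]:
    """Across experiments, scale each experiment's activities by the mean
    wild-type activity over all experiments (the pre-test normalization)."""
    wt_mean = float(np.mean([e[wildtype] for e in per_experiment]))
    if wt_mean <= 0:
        raise ValueError("non-positive mean wild-type activity")
    out: dict[str, list[float]] = {}
    for e in per_experiment:
        for c, v in e.items():
            out.setdefault(c, []).append(v / wt_mean)
    return out


def luciferase_deletion_test(
    wildtype: Sequence[float], deleted: Sequence[float]
) -> TestResult:
    """Pooled-variance two-sample t-test, lower tail: H1 deleted < wild-type."""
    if len(wildtype) < 2 or len(deleted) < 2:
        raise ValueError("need >= 2 replicates per construct")
    t_stat, _ = stats.ttest_ind(deleted, wildtype, equal_var=True)
    df = len(wildtype) + len(deleted) - 2
    p = float(stats.t.cdf(t_stat, df=df))
    return TestResult(float(t_stat), df, "lower", p, "pooled-variance t (lower tail)")


def significance_stars(p: float) -> str:
    """Fig.-style annotation: * <0.05, ** <0.01, *** <0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
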