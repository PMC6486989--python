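"""TE-subfamily enrichment in ChIP-seq peaks under a circular-rotation null.

The null model rotates each chromosome's peak set by an independent uniform
offset (peaks wrapping past the chromosome end are split in two but still
count as one peak), re-counts peak/subfamily coincidences, and averages over
permutations. Each subfamily is then tested with a one-sided (upper tail)
binomial test at p0 = expected_mean / n_peaks, Bonferroni-corrected over the
full subfamily universe, and summarised by the enrichment ratio
observed / expected_mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomeTable, GenomicInterval, TECopy


@dataclass(frozen=True)
class PeakSet:
    """A labelled ChIP-seq peak collection for one transcription factor."""

    tf_name: str
    source: str
    peaks: tuple[GenomicInterval, ...]

    @property
    def n_total(self) -> int:
        return len(self.peaks)


@dataclass(frozen=True)
class EnrichmentResult:
    subfamily: str
    te_class: str
    te_family: str
    observed: int
    expected_mean: float
    p0: float
    p_value: float
    p_adj: float
    enrichment_ratio: float
    n_perm: int

    @property
    def significant(self) -> bool:
        return self.p_adj < 0.05


@dataclass(frozen=True)
class OverlapCounts:
    """Distinct-peak overlap counts per subfamily plus the any-TE count."""

    per_subfamily: dict[str, int]
    any_te: int


class _PermutationEngine:
    """Array-based peak/TE overlap counter reused across rotations.

    Peaks and TE copies are regrouped per chromosome once; each call to
    :meth:`count` applies per-chromosome circular offsets (splitting wrapped
    peaks) and returns distinct-peak counts per subfamily in the universe
    order, plus the count of peaks hitting any TE.
    """

    def __init__(
        self,
        peaks: Sequence[GenomicInterval],
        te_copies: Sequence[TECopy],
        genome: GenomeTable,
    ):
        genome.validate(peaks)
        genome.validate([c.interval for c in te_copies])
        self.genome = genome
        self.universe = sorted({c.te_subfamily for c in te_copies})
        self._sub_index = {s: i for i, s in enumerate(self.universe)}
        self.n_peaks = len(peaks)

        self._peaks: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        by_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for pid, p in enumerate(peaks):
            by_chrom.setdefault(p.chrom, []).append((p.start, p.end, pid))
        for chrom, rows in by_chrom.items():
            arr = np.array(rows, dtype=np.int64)
            self._peaks[chrom] = (arr[:, 0], arr[:, 1], arr[:, 2])

        self._te: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        te_by_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for c in te_copies:
            te_by_chrom.setdefault(c.interval.chrom, []).append(
                (c.interval.start, c.interval.end, self._sub_index[c.te_subfamily])
            )
        for chrom, rows in te_by_chrom.items():
            arr = np.array(rows, dtype=np.int64)
            order = np.argsort(arr[:, 2], kind="stable")
            arr = arr[order]
            sub_ids = arr[:, 2]
            # contiguous runs of each subfamily for a single reduceat pass
            boundaries = np.flatnonzero(np.r_[True, np.diff(sub_ids) != 0])
            self._te[chrom] = (arr[:, 0], arr[:, 1], boundaries, sub_ids[boundaries])

    def count(self, offsets: Mapping[str, int] | None = None) -> OverlapCounts:
        counts = np.zeros(len(self.universe), dtype=np.int64)
        any_te = 0
        for chrom, (ps, pe, pid) in self._peaks.items():
            te = self._te.get(chrom)
            if te is None:
                continue
            ts, te_e, boundaries, run_subs = te
            off = 0 if offsets is None else int(offsets.get(chrom, 0))
            if off:
                L = self.genome.length(chrom)
                ns = (ps + off) % L
                ne = ns + (pe - ps)
                wrap = ne > L
                if wrap.any():
                    # wrapped peaks become two fragments sharing one peak id
                    ws, we, wid = ns[wrap], ne[wrap], pid[wrap]
                    ns = np.concatenate([ns[~wrap], ws, np.zeros(wrap.sum(), dtype=np.int64)])
                    ne = np.concatenate([ne[~wrap], np.full(wrap.sum(), L, dtype=np.int64),
                                         we - L])
                    ids = np.concatenate([pid[~wrap], wid, wid])
                else:
                    ids = pid
                ps_c, pe_c = ns, ne
            else:
                ps_c, pe_c, ids = ps, pe, pid
            ov = (ps_c[:, None] < te_e[None, :]) & (pe_c[:, None] > ts[None, :])
            any_rows = ov.any(axis=1)
            any_te += np.unique(ids[any_rows]).size
            hits = np.bitwise_or.reduceat(ov, boundaries, axis=1)
            for k, sub in enumerate(run_subs):
                rows = hits[:, k]
                if rows.any():
                    counts[sub] += np.unique(ids[rows]).size
        return OverlapCounts(
            per_subfamily=dict(zip(self.universe, counts.tolist())),
            any_te=int(any_te),
        )


def count_peak_subfamily_overlaps(
    peaks: Sequence[GenomicInterval],
    te_copies: Sequence[TECopy],
    genome: GenomeTable | None = None,
) -> OverlapCounts:
    """Distinct peaks overlapping >=1 copy of each subfamily (one peak may count
    toward several subfamilies, but at most once per subfamily), plus the count
    of peaks overlapping any TE."""
    if genome is None:
        genome = _bounding_genome(peaks, te_copies)
    return _PermutationEngine(peaks, te_copies, genome).count()


def _bounding_genome(
    peaks: Sequence[GenomicInterval], te_copies: Sequence[TECopy]
) -> GenomeTable:
    ends: dict[str, int] = {}
    for iv in list(peaks) + [c.interval for c in te_copies]:
        ends[iv.chrom] = max(ends.get(iv.chrom, 0), iv.end)
    return GenomeTable(ends.items())


def rotate_peaks(
    peaks: Sequence[GenomicInterval],
    genome: GenomeTable,
    rng_seed: int | np.random.Generator = 0,
    offsets: Mapping[str, int] | None = None,
) -> list[GenomicInterval]:
    """Circularly shift each chromosome's peaks by an independent uniform offset.

    A peak wrapping past the chromosome end is split into an end segment and a
    start segment; fragments inherit the source peak's index in ``name`` so a
    split peak still counts once. Explicit ``offsets`` override the random
    draw (used for exact all-offset enumeration).
    """
    genome.validate(peaks)
    if offsets is None:
        rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
               else np.random.default_rng(rng_seed))
        offsets = {c: int(rng.integers(0, L)) for c, L in genome.items()}
    out: list[GenomicInterval] = []
    for pid, p in enumerate(peaks):
        L = genome.length(p.chrom)
        off = int(offsets.get(p.chrom, 0))
        s = (p.start + off) % L
        e = s + len(p)
        name = p.name or str(pid)
        if e <= L:
            out.append(GenomicInterval(p.chrom, s, e, p.strand, name))
        else:
            out.append(GenomicInterval(p.chrom, s, L, p.strand, name))
            out.append(GenomicInterval(p.chrom, 0, e - L, p.strand, name))
    return out


def expected_overlap(
    peaks: Sequence[GenomicInterval],
    te_copies: Sequence[TECopy],
    genome: GenomeTable,
    n_perm: int = 10_000,
    rng_seed: int = 0,
) -> dict[str, float]:
    """Mean per-subfamily overlap count over ``n_perm`` circular rotations."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    engine = _PermutationEngine(peaks, te_copies, genome)
    rng = np.random.default_rng(rng_seed)
    totals = np.zeros(len(engine.universe), dtype=np.float64)
    for _ in range(n_perm):
        offsets = {c: int(rng.integers(0, L)) for c, L in genome.items()}
        counts = engine.count(offsets)
        totals += np.array([counts.per_subfamily[s] for s in engine.universe])
    return dict(zip(engine.universe, (totals / n_perm).tolist()))


def exact_expected_overlap(
    peaks: Sequence[GenomicInterval],
    te_copies: Sequence[TECopy],
    genome: GenomeTable,
) -> dict[str, float]:
    """Exact expectation by enumerating every integer offset (single-chromosome
    genomes only; the per-chromosome offsets would otherwise be a product space)."""
    if len(genome) != 1:
        raise ValueError("exact enumeration requires a single-chromosome genome")
    chrom, L = genome.items()[0]
    engine = _PermutationEngine(peaks, te_copies, genome)
    totals = np.zeros(len(engine.universe), dtype=np.float64)
    for off in range(L):
        counts = engine.count({chrom: off})
        totals += np.array([counts.per_subfamily[s] for s in engine.universe])
    return dict(zip(engine.universe, (totals / L).tolist()))


def binomial_enrichment(
    observed: int,
    expected_mean: float,
    n_total: int,
    n_subfamilies: int,
    *,
    subfamily: str = "",
    te_class: str = "",
    te_family: str = "",
    n_perm: int = 10_000,
) -> EnrichmentResult:
    """One-sided binomial enrichment test for a single subfamily.

    p0 = expected_mean / n_total, floored at 1/(n_perm * n_total) when the
    permutations produced zero expected overlap; p = P(X >= observed) for
    X ~ Binomial(n_total, p0); Bonferroni over ``n_subfamilies``.
    """
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if n_subfamilies < 1:
        raise ValueError("n_subfamilies must be >= 1")
    if not 0 <= observed <= n_total:
        raise ValueError(f"observed ({observed}) outside [0, n_total={n_total}]")
    p0 = expected_mean / n_total
    if p0 == 0.0:
        p0 = 1.0 / (n_perm * n_total)
    p0 = min(p0, 1.0)
    p_value = float(stats.binom.sf(observed - 1, n_total, p0))
    p_adj = min(1.0, p_value * n_subfamilies)
    if expected_mean > 0:
        ratio = observed / expected_mean
    else:
        ratio = math.inf if observed > 0 else 0.0
    return EnrichmentResult(
        subfamily=subfamily, te_class=te_class, te_family=te_family,
        observed=observed, expected_mean=expected_mean, p0=p0,
        p_value=p_value, p_adj=p_adj, enrichment_ratio=ratio, n_perm=n_perm,
    )


def significance_threshold(n_subfamilies: int, alpha: float = 0.05) -> float:
    """Bonferroni per-test threshold alpha / n_subfamilies."""
    if n_subfamilies < 1:
        raise ValueError("n_subfamilies must be >= 1")
    return alpha / n_subfamilies


def run_enrichment(
    peaks: Sequence[GenomicInterval],
    te_copies: Sequence[TECopy],
    genome: GenomeTable,
    n_perm: int = 10_000,
    rng_seed: int = 0,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Full enrichment scan: observed counts, rotation-null expectations and a
    Bonferroni-corrected binomial test for every subfamily in the TE table.

    The subfamily universe (and the Bonferroni divisor) is all subfamilies
    present in the table, not only those with observed overlap.
    """
    engine = _PermutationEngine(peaks, te_copies, genome)
    observed = engine.count()
    expected = expected_overlap(peaks, te_copies, genome, n_perm=n_perm, rng_seed=rng_seed)
    meta = {}
    for c in te_copies:
        meta.setdefault(c.te_subfamily, (c.te_class, c.te_family))
    n_sub = len(engine.universe)
    return [
        binomial_enrichment(
            observed.per_subfamily[s], expected[s], len(peaks), n_sub,
            subfamily=s, te_class=meta[s][0], te_family=meta[s][1], n_perm=n_perm,
        )
        for s in engine.universe
    ]


def results_frame(results: Sequence[EnrichmentResult], alpha: float = 0.05) -> pd.DataFrame:
    n_sub = len(results)
    thresh = significance_threshold(n_sub, alpha) if n_sub else alpha
    df = pd.DataFrame(
        {
            "subfamily": [r.subfamily for r in results],
            "te_class": [r.te_class for r in results],
            "te_family": [r.te_family for r in results],
            "observed": [r.observed for r in results],
            "expected_mean": [r.expected_mean for r in results],
            "p0": [r.p0 for r in results],
            "p_value": [r.p_value for r in results],
            "p_adj": [r.p_adj for r in results],
            "enrichment_ratio": [r.enrichment_ratio for r in results],
        }
    )
    df["significant"] = (df["p_value"] < thresh).astype(int)
    return df


def write_enrichment_tsv(
    path: str | Path,
    results: Sequence[EnrichmentResult],
    *,
    seed: int,
    n_perm: int,
    peak_file: str = "-",
    alpha: float = 0.05,
) -> None:
    n_sub = len(results)
    thresh = significance_threshold(n_sub, alpha) if n_sub else alpha
    df = results_frame(results, alpha=alpha)
    with open(path, "w") as fh:
        fh.write(f"# seed={seed} n_perm={n_perm} peaks={peak_file} "
                 f"alpha={alpha} n_subfamilies={n_sub} threshold={thresh:.6g}\n")
        df.to_csv(fh, sep="\t", index=False)


def peak_te_summary(
    peak_sets: Sequence[PeakSet],
    te_copies: Sequence[TECopy],
    genome: GenomeTable | None = None,
) -> pd.DataFrame:
    """Per peak-set accounting: total peaks, peaks in any TE, percentage (1 dp)."""
    rows = []
    for ps in peak_sets:
        counts = count_peak_subfamily_overlaps(ps.peaks, te_copies, genome)
        rows.append(
            {
                "tf": ps.tf_name,
                "source": ps.source,
                "total_peaks": ps.n_total,
                "peaks_in_te": counts.any_te,
                "pct_in_te": percent_in_te(counts.any_te, ps.n_total),
            }
        )
    return pd.DataFrame(rows)


def percent_in_te(n_in_te: int, n_total: int) -> float:
    """Percentage of peaks in TEs, rounded to one decimal place (0.0 when empty)."""
    if n_total <= 0:
        return 0.0
    return round(100.0 * n_in_te / n_total, 1)
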