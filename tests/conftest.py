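"""Shared fixtures and independent brute-force oracles.

The oracles here are deliberately naive (pure-Python all-pairs / per-base
loops) so they stay independent of the vectorised implementation paths they
check.
"""

from __future__ import annotations

import numpy as np
import pytest

from texapt.intervals import GenomeTable, GenomicInterval, TECopy


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def oracle_pairs(query, subject, strand_match=False, min_overlap=1):
    """All-pairs overlap oracle, quadratic and deliberately simple."""
    out = []
    for qi, q in enumerate(query):
        for si, s in enumerate(subject):
            if q.chrom != s.chrom:
                continue
            if strand_match and q.strand != s.strand:
                continue
            if min(q.end, s.end) - max(q.start, s.start) >= min_overlap:
                out.append((qi, si))
    return sorted(out)


def oracle_bin_counts(window_start, n_bins, bin_size, tags):
    """Per-bin tag counts by direct per-(tag, bin) overlap enumeration."""
    counts = [0] * n_bins
    for t in tags:
        for b in range(n_bins):
            b0 = window_start + b * bin_size
            if t.start < b0 + bin_size and t.end > b0:
                counts[b] += 1
    return counts


def oracle_smooth(curve, bandwidth, bin_size=50):
    """Naive O(n^2) Epanechnikov Nadaraya-Watson smoother."""
    n = len(curve)
    out = []
    for i in range(n):
        num = den = 0.0
        for j in range(n):
            if np.isnan(curve[j]):
                continue
            u = abs(i - j) * bin_size / bandwidth
            if u <= 1.0:
                w = 0.75 * (1 - u * u)
                num += w * curve[j]
                den += w
        out.append(num / den if den > 0 else np.nan)
    return np.array(out)


def oracle_consensus_positions(copy: TECopy):
    """Per-base genomic -> consensus map, written out longhand."""
    iv = copy.interval
    G = iv.end - iv.start
    C = copy.rep_end - copy.rep_start + 1
    mapping = {}
    for g in range(iv.start, iv.end):
        o = (g - iv.start) * C // G
        mapping[g] = (copy.rep_end - o) if iv.strand == "-" else (copy.rep_start + o)
    return mapping


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=10_000,
                     max_len=300, stranded=False):
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        strand = ("+", "-")[int(rng.integers(0, 2))] if stranded else "."
        out.append(GenomicInterval(chrom, start, start + length, strand))
    return out


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_genome():
    return GenomeTable([("chr1", 10_000), ("chr2", 8_000)])


def make_copy(chrom, start, end, subfamily="MIRb", strand="+",
              rep_start=None, rep_end=None, consensus_length=None,
              te_class="SINE", te_family="MIR"):
    L = end - start
    return TECopy(
        interval=GenomicInterval(chrom, start, end, strand, name=subfamily),
        te_class=te_class, te_family=te_family, te_subfamily=subfamily,
        rep_start=rep_start or 1,
        rep_end=rep_end or L,
        consensus_length=consensus_length or max(L, rep_end or L),
    )
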