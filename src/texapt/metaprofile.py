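"""Histone-mark coverage metaprofiles around TE copies, bound vs unbound.

A 10 kb window centred on each TE copy's midpoint is divided into 200 bins
of 50 bp. Per bin, aligned tags overlapping the bin by >= 1 bp are counted
(a tag spanning a bin edge increments both bins) and converted to RPKM
(reads per kilobase per million mapped reads). Per anchor the RPKM is
averaged over replicate tracks, the pooled control mean is subtracted, and
the result is averaged over anchors; bins clipped at chromosome ends are
excluded with a per-bin effective n. Curves are smoothed by Nadaraya-Watson
regression with an Epanechnikov kernel.

Truncation profiles place each copy on its subfamily consensus via
RepStart/RepEnd and report the per-position fraction of copies covering it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .intervals import GenomeTable, GenomicInterval, TECopy, intersect

N_BINS = 200
BIN_SIZE = 50
HALF_WINDOW = N_BINS * BIN_SIZE // 2  # 5000 bp


@dataclass
class TagTrack:
    """Aligned sequencing tags (read spans) with the library-size total.

    ``total_mapped`` may exceed ``len(tags)`` when the file is a subset of the
    library, but must be positive. Tag lookup is by per-chromosome sorted
    arrays, so construction is O(n log n) and window queries are cheap.
    """

    label: str
    tags: list[GenomicInterval]
    total_mapped: int

    def __post_init__(self) -> None:
        if self.total_mapped <= 0:
            raise ValueError("total_mapped must be > 0")
        self._index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._max_len: int = 0
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for t in self.tags:
            by_chrom.setdefault(t.chrom, []).append((t.start, t.end, t.score))
            self._max_len = max(self._max_len, len(t))
        for chrom, rows in by_chrom.items():
            arr = np.array([(s, e) for s, e, _ in rows], dtype=np.int64)
            order = np.argsort(arr[:, 0], kind="stable")
            scores = np.array([sc for _, _, sc in rows])[order]
            self._index[chrom] = (arr[order, 0], arr[order, 1], scores)

    def query(self, chrom: str, start: int, end: int) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) of tags overlapping [start, end) by >= 1 bp."""
        idx = self._index.get(chrom)
        if idx is None:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        starts, ends, _ = idx
        lo = np.searchsorted(starts, start - self._max_len, side="left")
        hi = np.searchsorted(starts, end, side="left")
        s, e = starts[lo:hi], ends[lo:hi]
        keep = e > start
        return s[keep], e[keep]


@dataclass
class ProfileMatrix:
    """Per-anchor, per-bin normalized coverage for one group and mark."""

    anchors: list[str]
    values: np.ndarray  # shape (n_anchors, N_BINS); NaN where the window was clipped
    group: str = ""
    mark: str = ""

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != N_BINS:
            raise ValueError(f"values must have {N_BINS} columns")
        if self.values.shape[0] == 0:
            raise ValueError("empty profile: no anchors")

    @property
    def bin_centres(self) -> np.ndarray:
        """Offsets of bin centres from the anchor midpoint (-4975 .. +4975)."""
        return np.arange(N_BINS) * BIN_SIZE - HALF_WINDOW + BIN_SIZE // 2

    def summary(self) -> tuple[np.ndarray, np.ndarray]:
        """(per-bin mean over anchors ignoring clipped bins, per-bin effective n)."""
        n_eff = np.sum(~np.isnan(self.values), axis=0)
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(self.values, axis=0)
        mean[n_eff == 0] = np.nan
        return mean, n_eff


def stratify_by_binding(
    te_copies: Sequence[TECopy],
    subfamily: str,
    peaks: Sequence[GenomicInterval],
) -> tuple[list[TECopy], list[TECopy]]:
    """Partition a subfamily's copies into (bound, unbound) by >=1 bp peak overlap."""
    members = [c for c in te_copies if c.te_subfamily == subfamily]
    hits = {si for _, si in intersect(peaks, [c.interval for c in members])}
    bound = [c for i, c in enumerate(members) if i in hits]
    unbound = [c for i, c in enumerate(members) if i not in hits]
    return bound, unbound


def binned_rpkm(
    anchor: TECopy,
    track: TagTrack,
    genome: GenomeTable | None = None,
) -> np.ndarray:
    """Per-bin RPKM over the 10 kb window centred on the anchor midpoint.

    A tag increments every bin it overlaps by >= 1 bp.
    RPKM = count * 1e9 / (BIN_SIZE * total_mapped). Bins falling outside the
    chromosome are NaN (missing), not zero.
    """
    mid = anchor.interval.midpoint
    w0 = mid - HALF_WINDOW
    chrom = anchor.interval.chrom
    counts = np.zeros(N_BINS, dtype=np.int64)
    ts, te = track.query(chrom, max(w0, 0), w0 + 2 * HALF_WINDOW)
    if ts.size:
        first = np.clip((ts - w0) // BIN_SIZE, 0, N_BINS - 1)
        last = np.clip(-((w0 - te) // BIN_SIZE) - 1, 0, N_BINS - 1)  # ceil((te-w0)/B)-1
        np.add.at(counts, first, 1)
        over = last + 1
        np.subtract.at(counts, over[over < N_BINS], 1)
        counts = np.cumsum(counts)
    rpkm = counts * 1e9 / (BIN_SIZE * track.total_mapped)
    edges = w0 + np.arange(N_BINS + 1) * BIN_SIZE
    missing = edges[:-1] < 0
    if genome is not None and chrom in genome:
        missing |= edges[1:] > genome.length(chrom)
    rpkm = rpkm.astype(float)
    rpkm[missing] = np.nan
    return rpkm


def aggregate_profile(
    anchors: Sequence[TECopy],
    replicate_tracks: Sequence[TagTrack],
    control_tracks: Sequence[TagTrack] = (),
    genome: GenomeTable | None = None,
    group: str = "",
    mark: str = "",
) -> ProfileMatrix:
    """Replicate-mean RPKM per anchor, minus the pooled control mean per anchor.

    Order of operations is fixed: mean over replicates (per bin, per anchor),
    then control subtraction (per bin, per anchor), then the anchor mean is
    taken downstream via :meth:`ProfileMatrix.summary`.
    """
    if not anchors:
        raise ValueError("empty profile: no anchors")
    if not replicate_tracks:
        raise ValueError("at least one replicate track required")
    values = np.empty((len(anchors), N_BINS))
    with warnings.catch_warnings():
        # clipped bins are NaN in every track; the all-NaN mean is the intended result
        warnings.simplefilter("ignore", category=RuntimeWarning)
        for i, a in enumerate(anchors):
            rep = np.nanmean(
                np.stack([binned_rpkm(a, t, genome) for t in replicate_tracks]), axis=0
            )
            if control_tracks:
                ctrl = np.nanmean(
                    np.stack([binned_rpkm(a, t, genome) for t in control_tracks]), axis=0
                )
                rep = rep - ctrl
            values[i] = rep
    names = [f"{a.te_subfamily}:{a.interval.chrom}:{a.interval.start}" for a in anchors]
    return ProfileMatrix(anchors=names, values=values, group=group, mark=mark)


def smooth_profile(
    curve: np.ndarray,
    bandwidth_bp: float = 150.0,
    bin_size: int = BIN_SIZE,
) -> np.ndarray:
    """Nadaraya-Watson smoothing with the Epanechnikov kernel K(u)=0.75(1-u^2).

    ``u`` is genomic distance between bin centres over ``bandwidth_bp``; NaN
    bins neither contribute nor poison their neighbours. Constant input is
    returned unchanged (kernel weights normalise).
    """
    curve = np.asarray(curve, dtype=float)
    n = curve.size
    pos = np.arange(n) * bin_size
    u = (pos[:, None] - pos[None, :]) / bandwidth_bp
    w = 0.75 * (1.0 - u**2)
    w[np.abs(u) > 1.0] = 0.0
    valid = ~np.isnan(curve)
    w = w * valid[None, :]
    denom = w.sum(axis=1)
    num = w @ np.where(valid, curve, 0.0)
    out = np.full(n, np.nan)
    ok = denom > 0
    out[ok] = num[ok] / denom[ok]
    return out


def truncation_profile(te_copies: Sequence[TECopy]) -> np.ndarray:
    """Per-consensus-position coverage fraction for a group of copies.

    Position j (1-based) gets (#copies with rep_start <= j <= rep_end) / group
    size; the vector length is the group's consensus length.
    """
    if not te_copies:
        raise ValueError("empty group")
    lengths = {c.consensus_length for c in te_copies}
    if len(lengths) != 1:
        raise ValueError("group mixes consensus lengths; split by subfamily first")
    L = lengths.pop()
    cov = np.zeros(L + 1, dtype=np.int64)
    for c in te_copies:
        cov[c.rep_start - 1] += 1
        cov[c.rep_end] -= 1
    return np.cumsum(cov[:-1]) / len(te_copies)


def mapq_filter_variant(track: TagTrack, min_quality: float) -> TagTrack:
    """Drop tags with score (BED column 5, mapping quality) below ``min_quality``;
    ``total_mapped`` is recomputed as the retained count."""
    kept = [t for t in track.tags if t.score >= min_quality]
    if not kept:
        raise ValueError("no tags retained at this quality threshold")
    return TagTrack(label=track.label, tags=kept, total_mapped=len(kept))


def profile_table(
    bound: ProfileMatrix,
    unbound: ProfileMatrix,
    bandwidth_bp: float = 150.0,
):
    """Side-by-side bound/unbound summary as a DataFrame (the CLI output)."""
    import pandas as pd

    b_mean, b_n = bound.summary()
    u_mean, u_n = unbound.summary()
    return pd.DataFrame(
        {
            "bin_centre_offset": bound.bin_centres,
            "bound_mean": b_mean,
            "bound_smoothed": smooth_profile(b_mean, bandwidth_bp),
            "bound_n": b_n,
            "unbound_mean": u_mean,
            "unbound_smoothed": smooth_profile(u_mean, bandwidth_bp),
            "unbound_n": u_n,
        }
    )
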