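"""Hierarchical discovery of TE-derived promoters of disease-associated genes.

Two procedures live here:

* :func:`annotate_probes` — assign differential-expression microarray probes
  to transcripts by priority tier (mRNA > lncRNA tier 1 > lncRNA tier 2),
  using strand-matched, exon-aware overlap; a probe takes ALL matches from
  the highest tier that hits and nothing from lower tiers.
* :func:`discover_te_promoters` — the intersection funnel: CAGE clusters
  within a window of a TF binding site, then overlapping a TE copy, then
  overlapping (strand-matched) the promoter region around an annotated
  transcript's 5' end. One candidate row per (cluster, transcript, TE, TF);
  a gene-level summary deduplicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .intervals import (
    GenomeTable,
    GenomicInterval,
    TECopy,
    TranscriptModel,
    intersect,
    split_intersect,
    window_intersect,
)

TIER_ORDER = ("mRNA", "lncRNA_tier1", "lncRNA_tier2")


@dataclass(frozen=True)
class ProbeAlignment:
    probe_id: str
    interval: GenomicInterval


@dataclass(frozen=True)
class CageCluster:
    cluster_id: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError("CAGE clusters must be stranded")


@dataclass(frozen=True)
class PromoterCandidate:
    gene_id: str
    transcript_id: str
    cage_id: str
    te: TECopy
    tf_name: str
    promoter: GenomicInterval


@dataclass(frozen=True)
class ProbeAnnotation:
    tier: str
    transcript_ids: tuple[str, ...]


def annotate_probes(
    probes: Sequence[ProbeAlignment],
    tiers: Mapping[str, Sequence[TranscriptModel]],
) -> tuple[dict[str, ProbeAnnotation], int]:
    """Annotate each probe with ALL transcripts from the highest-priority tier
    producing >= 1 strand-matched exonic overlap; return (annotations, n_dropped).

    ``tiers`` maps tier name -> transcripts and is consulted in TIER_ORDER;
    probes matching no tier are dropped (and counted), as in a hierarchical
    re-annotation of pre-aligned probes.
    """
    unknown = set(tiers) - set(TIER_ORDER)
    if unknown:
        raise ValueError(f"unknown tiers {sorted(unknown)}; expected {TIER_ORDER}")
    remaining = list(range(len(probes)))
    annotations: dict[str, ProbeAnnotation] = {}
    for tier in TIER_ORDER:
        transcripts = list(tiers.get(tier, ()))
        if not transcripts or not remaining:
            continue
        ivs = [probes[i].interval for i in remaining]
        pairs = split_intersect(ivs, transcripts, strand_match=True)
        by_probe: dict[int, list[str]] = {}
        for qi, ti in pairs:
            by_probe.setdefault(qi, []).append(transcripts[ti].transcript_id)
        matched_local = sorted(by_probe)
        for qi in matched_local:
            pid = probes[remaining[qi]].probe_id
            annotations[pid] = ProbeAnnotation(tier, tuple(sorted(set(by_probe[qi]))))
        matched_global = {remaining[qi] for qi in matched_local}
        remaining = [i for i in remaining if i not in matched_global]
    return annotations, len(remaining)


def promoter_region(
    transcript: TranscriptModel,
    half_width: int = 1000,
    genome: GenomeTable | None = None,
    mode: str = "centered",
) -> GenomicInterval:
    """Promoter interval around the transcript 5' end.

    ``centered`` (default): TSS +/- half_width. ``upstream``: the 2*half_width
    bp strictly upstream of the TSS. Clipped at chromosome bounds; strand
    inherited from the transcript.
    """
    iv = transcript.interval
    if mode == "centered":
        if iv.strand == "+":
            start, end = iv.start - half_width, iv.start + half_width
        else:
            start, end = iv.end - half_width, iv.end + half_width
    elif mode == "upstream":
        if iv.strand == "+":
            start, end = iv.start - 2 * half_width, iv.start
        else:
            start, end = iv.end, iv.end + 2 * half_width
    else:
        raise ValueError("mode must be 'centered' or 'upstream'")
    start = max(0, start)
    if genome is not None and iv.chrom in genome:
        end = min(end, genome.length(iv.chrom))
    return GenomicInterval(iv.chrom, start, end, iv.strand, name=transcript.transcript_id)


def discover_te_promoters(
    cage: Sequence[CageCluster],
    peak_sets: Mapping[str, Sequence[GenomicInterval]],
    te_copies: Sequence[TECopy],
    transcripts: Sequence[TranscriptModel],
    window: int = 300,
    promoter_half_width: int = 1000,
    genome: GenomeTable | None = None,
    promoter_mode: str = "centered",
    gene_allow_list: Sequence[str] | None = None,
) -> tuple[list[PromoterCandidate], "Funnel"]:
    """Run the promoter-discovery funnel and return (candidates, stage counts).

    Stages, in fixed order:
      1. CAGE clusters within ``window`` bp of >= 1 TF peak (strand-blind,
         pooled over TFs; TF names recorded);
      2. of those, clusters overlapping >= 1 TE copy (strand-blind);
      3. of those, clusters overlapping a promoter region (strand-matched)
         of an annotated transcript.
    One candidate per (cluster, transcript, TE, TF) combination.
    """
    if not cage:
        raise ValueError("empty CAGE input")
    cage_ivs = [c.interval for c in cage]

    pooled: list[GenomicInterval] = []
    peak_tf: list[str] = []
    for tf, peaks in peak_sets.items():
        pooled.extend(peaks)
        peak_tf.extend([tf] * len(peaks))

    near_tf: dict[int, set[str]] = {}
    for qi, sj in window_intersect(cage_ivs, pooled, w=window, genome=genome):
        near_tf.setdefault(qi, set()).add(peak_tf[sj])
    stage1 = sorted(near_tf)

    te_ivs = [c.interval for c in te_copies]
    s1_ivs = [cage_ivs[i] for i in stage1]
    in_te: dict[int, list[int]] = {}
    for qi, sj in intersect(s1_ivs, te_ivs):
        in_te.setdefault(stage1[qi], []).append(sj)
    stage2 = sorted(in_te)

    promoters = [
        promoter_region(t, promoter_half_width, genome, promoter_mode)
        for t in transcripts
    ]
    s2_ivs = [cage_ivs[i] for i in stage2]
    in_prom: dict[int, list[int]] = {}
    for qi, sj in intersect(s2_ivs, promoters, strand_match=True):
        in_prom.setdefault(stage2[qi], []).append(sj)
    stage3 = sorted(in_prom)

    candidates: list[PromoterCandidate] = []
    for ci in stage3:
        for ti in in_prom[ci]:
            t = transcripts[ti]
            if gene_allow_list is not None and t.gene_id not in gene_allow_list:
                continue
            for te_j in in_te[ci]:
                for tf in sorted(near_tf[ci]):
                    candidates.append(
                        PromoterCandidate(
                            gene_id=t.gene_id,
                            transcript_id=t.transcript_id,
                            cage_id=cage[ci].cluster_id,
                            te=te_copies[te_j],
                            tf_name=tf,
                            promoter=promoters[ti],
                        )
                    )
    kept_clusters = {c.cage_id for c in candidates}
    funnel = Funnel(
        n_cage=len(cage),
        n_near_tfbs=len(stage1),
        n_in_te=len(stage2),
        n_in_promoter=len(stage3) if gene_allow_list is None else len(kept_clusters),
        n_genes=len({c.gene_id for c in candidates}),
        n_transcripts=len({c.transcript_id for c in candidates}),
    )
    return candidates, funnel


@dataclass(frozen=True)
class Funnel:
    """Stage counts of the discovery funnel (non-increasing along the chain)."""

    n_cage: int
    n_near_tfbs: int
    n_in_te: int
    n_in_promoter: int
    n_genes: int
    n_transcripts: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": [
                    "cage_clusters",
                    "near_tfbs",
                    "in_te",
                    "in_promoter",
                    "genes",
                    "transcripts",
                ],
                "count": [
                    self.n_cage,
                    self.n_near_tfbs,
                    self.n_in_te,
                    self.n_in_promoter,
                    self.n_genes,
                    self.n_transcripts,
                ],
            }
        )


def candidates_frame(candidates: Sequence[PromoterCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [c.gene_id for c in candidates],
            "transcript": [c.transcript_id for c in candidates],
            "cage_id": [c.cage_id for c in candidates],
            "te_subfamily": [c.te.te_subfamily for c in candidates],
            "te_coords": [
                f"{c.te.interval.chrom}:{c.te.interval.start}-{c.te.interval.end}"
                for c in candidates
            ],
            "tf": [c.tf_name for c in candidates],
            "promoter_coords": [
                f"{c.promoter.chrom}:{c.promoter.start}-{c.promoter.end}"
                for c in candidates
            ],
        }
    )
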