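"""Synthetic-data generator for the whole pipeline, with recorded ground truth.

The generator emulates the input universe of a TE regulatory-genomics study:
a multi-chromosome genome partitioned into TE copies from a catalogue of
named subfamilies (with realistic class/family nesting and truncation),
ChIP-seq peak sets with configurable per-subfamily enrichment over a uniform
background, histone-mark tag tracks with elevated coverage around TF-bound
copies, a transcriptome with CAGE clusters at transcript 5' ends (including
planted TE-derived promoter positives and single-violation decoys),
microarray probes on exons, paired tumour/normal methylation counts with a
configurable hypomethylation effect, DNase counts with a configurable
sensitivity ratio, and dual-luciferase plates.

Everything is deterministic under ``SimulationConfig.seed`` (byte-identical
output trees), and every planted object is resolvable through the emitted
:class:`GroundTruth`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .epistats import LuciferasePlate
from .intervals import (
    GenomeTable,
    GenomicInterval,
    TECopy,
    TranscriptModel,
    intersect,
    write_bed,
    write_bed12,
    write_te_table,
)
from .metaprofile import TagTrack
from .promoters import CageCluster, ProbeAlignment

_SLOT = 4000  # bp reserved per planted promoter construct

DECOY_CLASSES = ("far_from_tfbs", "outside_te", "outside_promoter", "wrong_strand")


@dataclass(frozen=True)
class SubfamilySpec:
    """Catalogue entry: one TE subfamily and its truncation behaviour."""

    name: str
    te_class: str
    te_family: str
    consensus_length: int
    n_copies: int
    p_full_length: float = 0.4
    min_fraction: float = 0.3  # shortest truncated copy, as a consensus fraction


def default_catalogue() -> tuple[SubfamilySpec, ...]:
    """Thirty subfamilies spanning the four major TE classes.

    Consensus lengths are scaled to suit a megabase-scale synthetic genome
    while keeping the class-typical ordering (LINEs longest, SINEs shortest).
    """
    spec: list[tuple[str, str, str, int, int]] = []
    sine = [("MIRb", "MIR", 260), ("MIR3", "MIR", 220), ("MIR", "MIR", 260),
            ("AluJb", "Alu", 310), ("AluSx", "Alu", 310), ("AluY", "Alu", 300),
            ("FLAM_C", "Alu", 140)]
    line = [("L2a", "L2", 420), ("L2b", "L2", 400), ("L2c", "L2", 380),
            ("L1PA2", "L1", 1200), ("L1PA4", "L1", 1100), ("L1MB7", "L1", 900),
            ("L1ME1", "L1", 800)]
    ltr = [("LTR7C", "ERV1", 450), ("LTR12C", "ERV1", 600), ("MER41B", "ERV1", 520),
           ("LTR10A", "ERV1", 470), ("MLT1K", "ERVL-MaLR", 400),
           ("THE1B", "ERVL-MaLR", 350), ("MSTA", "ERVL-MaLR", 380),
           ("LTR16A", "ERVL", 420)]
    dna = [("MER136", "hAT-Tip100", 240), ("Charlie1a", "hAT-Charlie", 400),
           ("MER20", "hAT-Charlie", 220), ("MER5A", "hAT-Charlie", 160),
           ("Tigger1", "TcMar-Tigger", 650), ("MER44B", "TcMar-Tigger", 500),
           ("Tc2", "TcMar-Tc2", 480), ("MER2", "TcMar-Tigger", 340)]
    for name, fam, L in sine:
        spec.append((name, "SINE", fam, L, 220))
    for name, fam, L in line:
        spec.append((name, "LINE", fam, L, 150))
    for name, fam, L in ltr:
        spec.append((name, "LTR", fam, L, 150))
    for name, fam, L in dna:
        spec.append((name, "DNA", fam, L, 140))
    return tuple(
        SubfamilySpec(name, cls, fam, L, n) for name, cls, fam, L, n in spec
    )


@dataclass
class SimulationConfig:
    """All knobs of the generator; every stochastic choice flows from ``seed``."""

    seed: int = 0
    # genome
    n_chroms: int = 4
    chrom_length: int = 2_000_000
    subfamilies: tuple[SubfamilySpec, ...] = field(default_factory=default_catalogue)
    # peaks
    tfs: tuple[str, ...] = ("CEBPB",)
    n_peaks: int = 2000
    peak_length_range: tuple[int, int] = (150, 250)
    planted_enrichment: dict[str, float] = field(default_factory=dict)
    # tag tracks
    marks: tuple[str, ...] = ("H3K27ac",)
    n_replicates: int = 2
    tag_rate: float = 0.02  # background tags per bp
    tag_length: int = 50
    bound_fold: float = 5.0
    bound_half_width: int = 500
    profile_subfamily: str = "MIRb"
    # transcriptome
    n_genes: int = 60
    tier_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    cage_fraction: float = 0.9
    n_probes_unannotated: int = 5
    n_promoter_positives: int = 20
    n_decoys_per_class: int = 50
    cage_window: int = 300
    promoter_half_width: int = 1000
    # paired counts
    n_methylation_pairs: int = 6
    methylation_delta: float = -0.2
    methylation_sd: float = 0.15
    methylation_baseline: float = 0.6
    methylation_between_sd: float = 0.05
    methylation_subfamily_count: int = 20_000
    dnase_n: tuple[int, int] = (5000, 5000)
    dnase_p: tuple[float, float] = (0.04, 0.02)
    # luciferase
    luciferase_effects: dict[str, float] = field(
        default_factory=lambda: {"wild-type": 1.0, "TE-deleted": 0.15,
                                 "positive control": 2.0}
    )
    luciferase_cv: float = 0.1
    n_luciferase_experiments: int = 3

    def __post_init__(self) -> None:
        probs = [self.cage_fraction, *self.tier_fractions, *self.dnase_p,
                 self.methylation_baseline]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_chroms <= 0 or self.chrom_length <= 0 or self.n_peaks < 0:
            raise ValueError("counts must be positive")
        if abs(sum(self.tier_fractions) - 1.0) > 1e-9:
            raise ValueError("tier_fractions must sum to 1")

    @property
    def n_constructs(self) -> int:
        return self.n_promoter_positives + len(DECOY_CLASSES) * self.n_decoys_per_class

    def construct_zone_length(self) -> int:
        if self.n_constructs == 0:
            return 0
        per_chrom = -(-self.n_constructs // self.n_chroms)  # ceil
        return per_chrom * _SLOT + 1000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "subfamilies" in raw:
            raw["subfamilies"] = tuple(SubfamilySpec(**s) for s in raw["subfamilies"])
        for key in ("tfs", "marks", "peak_length_range", "tier_fractions",
                    "dnase_n", "dnase_p"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        raw["subfamilies"] = [dataclasses.asdict(s) for s in self.subfamilies]
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class GroundTruth:
    """Everything the generator planted, resolvable to emitted records by id."""

    planted_enrichment: dict[str, float]
    background_overlap_prob: dict[str, float]
    bound_copy_names: list[str]
    bound_fold: float
    probe_tiers: dict[str, str]
    positives: list[str]
    decoys: dict[str, str]  # cage id -> violated condition
    methylation_delta: float
    methylation_sd: float
    dnase_p: tuple[float, float]
    luciferase_effects: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


def _rngs(config: SimulationConfig) -> list[np.random.Generator]:
    children = np.random.SeedSequence(config.seed).spawn(6)
    return [np.random.default_rng(c) for c in children]


# ---------------------------------------------------------------------------
# genome and TE table
# ---------------------------------------------------------------------------

def simulate_genome(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[GenomeTable, list[TECopy]]:
    """Place non-overlapping TE copies uniformly on a multi-chromosome genome.

    Truncation draws set rep_start/rep_end; the genomic footprint equals the
    consensus span (the synthetic copies are ungapped). The terminal
    construct zone of each chromosome (if promoter constructs are configured)
    is kept free of random copies.
    """
    if rng is None:
        rng = _rngs(config)[0]
    genome = GenomeTable(
        (f"chr{i + 1}", config.chrom_length) for i in range(config.n_chroms)
    )
    zone = config.construct_zone_length()
    avail = config.chrom_length - zone

    copies_spec: list[tuple[SubfamilySpec, int, int]] = []  # (spec, rep_start, rep_end)
    for sub in config.subfamilies:
        for _ in range(sub.n_copies):
            L = sub.consensus_length
            if rng.random() < sub.p_full_length:
                rep_start, rep_end = 1, L
            else:
                min_len = max(30, int(sub.min_fraction * L))
                length = int(rng.integers(min_len, L + 1))
                rep_start = int(rng.integers(1, L - length + 2))
                rep_end = rep_start + length - 1
            copies_spec.append((sub, rep_start, rep_end))

    order = rng.permutation(len(copies_spec))
    chrom_of = rng.integers(0, config.n_chroms, size=len(copies_spec))
    te_copies: list[TECopy] = []
    for ci in range(config.n_chroms):
        mine = [int(k) for k in order if chrom_of[k] == ci]
        lengths = np.array(
            [copies_spec[k][2] - copies_spec[k][1] + 1 for k in mine], dtype=np.int64
        )
        free = avail - int(lengths.sum())
        if free < 0:
            raise ValueError(
                "TE catalogue does not fit the genome; increase chrom_length "
                "or thin the catalogue"
            )
        gaps = np.sort(rng.random(len(mine))) * free
        starts = (gaps + np.concatenate([[0], np.cumsum(lengths[:-1])])).astype(np.int64)
        for k, start, length in zip(mine, starts.tolist(), lengths.tolist()):
            sub, rep_start, rep_end = copies_spec[k]
            strand = "+" if rng.random() < 0.5 else "-"
            te_copies.append(
                TECopy(
                    interval=GenomicInterval(
                        f"chr{ci + 1}", start, start + length, strand, name=sub.name
                    ),
                    te_class=sub.te_class,
                    te_family=sub.te_family,
                    te_subfamily=sub.name,
                    rep_start=rep_start,
                    rep_end=rep_end,
                    consensus_length=sub.consensus_length,
                )
            )
    te_copies.sort(key=lambda c: (c.interval.chrom, c.interval.start))
    return genome, te_copies


def background_overlap_probability(
    te_copies: Sequence[TECopy], genome: GenomeTable, peak_length: int
) -> dict[str, float]:
    """P(uniformly placed peak of given length overlaps >= 1 copy) per subfamily,
    ignoring copy clustering (copies of one subfamily rarely adjoin)."""
    total = sum(L for _, L in genome.items())
    prob: dict[str, float] = {}
    for c in te_copies:
        prob[c.te_subfamily] = prob.get(c.te_subfamily, 0.0) + (
            len(c.interval) + peak_length - 1
        ) / total
    return {s: min(p, 1.0) for s, p in prob.items()}


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

def simulate_peaks(
    config: SimulationConfig,
    genome: GenomeTable,
    te_copies: Sequence[TECopy],
    rng: np.random.Generator | None = None,
    exclusion_zones: Sequence[GenomicInterval] = (),
) -> tuple[dict[str, list[GenomicInterval]], dict[str, float]]:
    """Peak BED per TF: planted subfamilies receive fold x background overlap,
    the remainder is uniform (rejected from ``exclusion_zones``)."""
    if rng is None:
        rng = _rngs(config)[1]
    lo, hi = config.peak_length_range
    mean_len = (lo + hi) // 2
    bg = background_overlap_probability(te_copies, genome, mean_len)
    by_sub: dict[str, list[TECopy]] = {}
    for c in te_copies:
        by_sub.setdefault(c.te_subfamily, []).append(c)

    chroms = genome.chroms
    excl_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for z in exclusion_zones:
        excl_by_chrom.setdefault(z.chrom, []).append((z.start, z.end))

    def _uniform_peak() -> GenomicInterval:
        for _ in range(1000):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            length = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(0, genome.length(chrom) - length))
            if any(start < e and start + length > s
                   for s, e in excl_by_chrom.get(chrom, ())):
                continue
            return GenomicInterval(chrom, start, start + length)
        raise RuntimeError("could not place a peak outside exclusion zones")

    peak_sets: dict[str, list[GenomicInterval]] = {}
    for tf in config.tfs:
        peaks: list[GenomicInterval] = []
        n_extra_total = 0
        for sub, fold in config.planted_enrichment.items():
            if fold <= 1.0 or sub not in by_sub:
                continue
            lam = config.n_peaks * bg.get(sub, 0.0) * (fold - 1.0)
            n_extra = int(rng.poisson(lam))
            n_extra_total += n_extra
            copies = by_sub[sub]
            for _ in range(n_extra):
                c = copies[int(rng.integers(0, len(copies)))]
                length = int(rng.integers(lo, hi + 1))
                iv = c.interval
                L = genome.length(iv.chrom)
                s_lo = max(0, iv.start - length + 1)
                s_hi = min(L - length, iv.end - 1)
                start = int(rng.integers(s_lo, s_hi + 1))
                peaks.append(GenomicInterval(iv.chrom, start, start + length))
        for _ in range(max(0, config.n_peaks - n_extra_total)):
            peaks.append(_uniform_peak())
        peak_sets[tf] = peaks
    return peak_sets, bg


# ---------------------------------------------------------------------------
# tag tracks
# ---------------------------------------------------------------------------

def simulate_tags(
    config: SimulationConfig,
    genome: GenomeTable,
    bound_copies: Sequence[TECopy],
    mark: str = "H3K27ac",
    rng: np.random.Generator | None = None,
) -> tuple[list[TagTrack], TagTrack, dict[str, int]]:
    """Poisson tag tracks: replicates with fold-elevated rate within
    +/- bound_half_width of bound-copy midpoints, plus a pure-background control.

    Returns (replicate tracks, control track, totals by label).
    """
    if rng is None:
        rng = _rngs(config)[2]
    tlen = config.tag_length

    def _background() -> list[GenomicInterval]:
        tags = []
        for chrom, L in genome.items():
            n = int(rng.poisson(config.tag_rate * L))
            starts = rng.integers(0, L - tlen, size=n)
            scores = rng.integers(0, 61, size=n)
            tags.extend(
                GenomicInterval(chrom, int(s), int(s) + tlen, score=float(q))
                for s, q in zip(starts.tolist(), scores.tolist())
            )
        return tags

    def _bound_extra() -> list[GenomicInterval]:
        tags = []
        hw = config.bound_half_width
        lam = (config.bound_fold - 1.0) * config.tag_rate * 2 * hw
        for c in bound_copies:
            iv = c.interval
            L = genome.length(iv.chrom)
            mid = iv.midpoint
            n = int(rng.poisson(lam))
            w_lo = max(0, mid - hw)
            w_hi = min(L - tlen, mid + hw - tlen)
            if w_hi <= w_lo:
                continue
            starts = rng.integers(w_lo, w_hi + 1, size=n)
            scores = rng.integers(0, 61, size=n)
            tags.extend(
                GenomicInterval(iv.chrom, int(s), int(s) + tlen, score=float(q))
                for s, q in zip(starts.tolist(), scores.tolist())
            )
        return tags

    replicates = []
    totals: dict[str, int] = {}
    for r in range(1, config.n_replicates + 1):
        tags = _background() + _bound_extra()
        label = f"{mark}_r{r}"
        replicates.append(TagTrack(label=label, tags=tags, total_mapped=len(tags)))
        totals[label] = len(tags)
    ctrl_tags = _background()
    control = TagTrack(label="input", tags=ctrl_tags, total_mapped=len(ctrl_tags))
    totals["input"] = len(ctrl_tags)
    return replicates, control, totals


# ---------------------------------------------------------------------------
# transcriptome, CAGE, probes, promoter constructs
# ---------------------------------------------------------------------------

@dataclass
class TranscriptomeSim:
    transcripts: dict[str, list[TranscriptModel]]  # tier -> models
    cage: list[CageCluster]
    probes: list[ProbeAlignment]
    extra_te: list[TECopy]          # construct TEs (merge into the TE table)
    extra_peaks: list[GenomicInterval]  # construct TFBSs (merge into tf[0]'s peaks)
    probe_tiers: dict[str, str]
    positives: list[str]
    decoys: dict[str, str]


def _construct_slots(config: SimulationConfig, genome: GenomeTable):
    zone = config.construct_zone_length()
    slots = []
    per_chrom = -(-config.n_constructs // config.n_chroms) if config.n_constructs else 0
    for chrom, L in genome.items():
        z0 = L - zone
        for k in range(per_chrom):
            slots.append((chrom, z0 + k * _SLOT))
    return slots[: config.n_constructs]


def _make_transcript(
    chrom: str, start: int, length: int, strand: str,
    tid: str, gid: str, tier: str, n_exons: int,
) -> TranscriptModel:
    end = start + length
    exon_len = min(200, length)
    if n_exons == 1:
        exons = ((start, end),)
    else:
        offs = [round(i * (length - exon_len) / (n_exons - 1)) for i in range(n_exons)]
        exons = tuple((start + o, start + o + exon_len) for o in offs)
    return TranscriptModel(
        interval=GenomicInterval(chrom, start, end, strand, name=f"{tid}|{gid}"),
        exons=exons, transcript_id=tid, gene_id=gid, tier=tier,
    )


def simulate_transcriptome(
    config: SimulationConfig,
    genome: GenomeTable,
    te_copies: Sequence[TECopy],
    rng: np.random.Generator | None = None,
) -> TranscriptomeSim:
    """Transcript tiers, CAGE clusters at 5' ends, probes on exons, and the
    planted promoter positives/decoys in the reserved construct zones.

    Random CAGE clusters are suppressed when they would overlap a TE, so the
    discovery truth set is exactly the planted positives. Decoys each violate
    exactly one discovery predicate.
    """
    if rng is None:
        rng = _rngs(config)[3]
    zone = config.construct_zone_length()
    tiers: dict[str, list[TranscriptModel]] = {
        "mRNA": [], "lncRNA_tier1": [], "lncRNA_tier2": []
    }
    tier_names = list(tiers)
    cage: list[CageCluster] = []
    probes: list[ProbeAlignment] = []
    probe_tiers: dict[str, str] = {}

    te_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c in te_copies:
        te_by_chrom.setdefault(c.interval.chrom, []).append(
            (c.interval.start, c.interval.end)
        )

    placed: dict[str, list[tuple[int, int]]] = {}
    chroms = genome.chroms
    draws = rng.random(config.n_genes)
    cum = np.cumsum(config.tier_fractions)
    for g in range(config.n_genes):
        tier = tier_names[int(np.searchsorted(cum, draws[g], side="right"))]
        for _ in range(200):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            length = int(rng.integers(2000, 6001))
            limit = genome.length(chrom) - zone - length - 1
            if limit <= 0:
                continue
            start = int(rng.integers(1000, limit))
            if any(start < e and start + length > s
                   for s, e in placed.get(chrom, ())):
                continue
            break
        else:
            raise RuntimeError("could not place a transcript without overlap")
        placed.setdefault(chrom, []).append((start, start + length))
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 6))
        tid, gid = f"TX{g:04d}", f"GENE{g:04d}"
        t = _make_transcript(chrom, start, length, strand, tid, gid, tier, n_exons)
        tiers[tier].append(t)

        if rng.random() < config.cage_fraction:
            w = int(rng.integers(20, 61))
            tss = t.tss
            c_start = max(0, tss - w // 2)
            c_iv = (c_start, c_start + w)
            hits_te = any(c_iv[0] < e and c_iv[1] > s
                          for s, e in te_by_chrom.get(chrom, ()))
            if not hits_te:
                cage.append(
                    CageCluster(f"cage_{g:04d}",
                                GenomicInterval(chrom, *c_iv, strand))
                )
        exon = t.exons[int(rng.integers(0, len(t.exons)))]
        if exon[1] - exon[0] >= 60:
            p_start = int(rng.integers(exon[0], exon[1] - 60 + 1))
            pid = f"probe_{g:04d}"
            probes.append(
                ProbeAlignment(pid, GenomicInterval(chrom, p_start, p_start + 60, strand))
            )
            probe_tiers[pid] = tier

    # unannotatable probes: intergenic, dropped by the hierarchical annotation
    for u in range(config.n_probes_unannotated):
        for _ in range(500):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            start = int(rng.integers(0, genome.length(chrom) - zone - 60))
            if not any(start < e and start + 60 > s
                       for s, e in placed.get(chrom, ())):
                probes.append(
                    ProbeAlignment(f"probe_u{u:03d}",
                                   GenomicInterval(chrom, start, start + 60, "+"))
                )
                break

    # planted constructs
    extra_te: list[TECopy] = []
    extra_peaks: list[GenomicInterval] = []
    positives: list[str] = []
    decoys: dict[str, str] = {}
    kinds = ["positive"] * config.n_promoter_positives
    for d in DECOY_CLASSES:
        kinds += [d] * config.n_decoys_per_class
    slots = _construct_slots(config, genome)
    assert len(slots) == len(kinds)
    n_tx = config.n_genes
    for k, ((chrom, slot), kind) in enumerate(zip(slots, kinds)):
        x = slot + 1000
        te = TECopy(
            interval=GenomicInterval(chrom, x, x + 200, "+", name="L1PA8"),
            te_class="LINE", te_family="L1", te_subfamily="L1PA8",
            rep_start=1, rep_end=200, consensus_length=1200,
        )
        cage_strand = "-" if kind == "wrong_strand" else "+"
        cid = f"construct_{kind}_{k:03d}"
        cluster = CageCluster(cid, GenomicInterval(chrom, x + 80, x + 120, cage_strand))
        peak = GenomicInterval(chrom, x + 220, x + 420, name=f"construct_{k:03d}")
        tid, gid = f"CTX{k:04d}", f"CGENE{k:04d}"
        transcript = _make_transcript(chrom, x + 100, 2500, "+", tid, gid, "mRNA", 2)

        if kind != "outside_te":
            extra_te.append(te)
        if kind != "far_from_tfbs":
            extra_peaks.append(peak)
        if kind != "outside_promoter":
            tiers["mRNA"].append(transcript)
            n_tx += 1
        cage.append(cluster)
        if kind == "positive":
            positives.append(cid)
        else:
            decoys[cid] = kind

    return TranscriptomeSim(
        transcripts=tiers, cage=cage, probes=probes,
        extra_te=extra_te, extra_peaks=extra_peaks,
        probe_tiers=probe_tiers, positives=positives, decoys=decoys,
    )


# ---------------------------------------------------------------------------
# paired counts and luciferase
# ---------------------------------------------------------------------------

def simulate_methylation_level_pairs(
    rng: np.random.Generator,
    n_pairs: int,
    delta: float,
    sd: float,
    baseline: float = 0.6,
    between_sd: float = 0.05,
) -> list[tuple[float, float]]:
    """(tumour, normal) normalized-level pairs whose differences are
    N(delta, sd^2); levels are clipped to (0.001, 0.999)."""
    out = []
    for _ in range(n_pairs):
        normal = float(np.clip(baseline + rng.normal(0.0, between_sd), 0.001, 0.999))
        tumour = float(np.clip(normal + rng.normal(delta, sd), 0.001, 0.999))
        out.append((tumour, normal))
    return out


def simulate_paired_counts(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Methylation and DNase count tables.

    Methylation: per pair, tumour/normal candidate counts chosen so the
    candidate/subfamily ratio carries the configured hypomethylation effect.
    DNase: binomial candidate counts at the configured per-cell-line
    sensitivities.
    """
    if rng is None:
        rng = _rngs(config)[4]
    S = config.methylation_subfamily_count
    rows = []
    pairs = simulate_methylation_level_pairs(
        rng, config.n_methylation_pairs, config.methylation_delta,
        config.methylation_sd, config.methylation_baseline,
        config.methylation_between_sd,
    )
    for i, (tum, norm) in enumerate(pairs, start=1):
        rows.append({"sample": f"pair{i}", "condition": "tumour",
                     "candidate_count": int(round(tum * S)), "subfamily_count": S})
        rows.append({"sample": f"pair{i}", "condition": "normal",
                     "candidate_count": int(round(norm * S)), "subfamily_count": S})
    methylation = pd.DataFrame(rows)

    (n1, n2), (p1, p2) = config.dnase_n, config.dnase_p
    dnase = pd.DataFrame(
        [
            {"sample": "MCF7", "condition": "MCF7",
             "candidate_count": int(rng.binomial(n1, p1)), "subfamily_count": n1},
            {"sample": "HMEC", "condition": "HMEC",
             "candidate_count": int(rng.binomial(n2, p2)), "subfamily_count": n2},
        ]
    )
    return methylation, dnase


def simulate_luciferase(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[LuciferasePlate]:
    """Triplicate firefly/Renilla plates for each construct and experiment,
    with multiplicative log-normal well noise."""
    if rng is None:
        rng = _rngs(config)[5]
    plates = []
    cv = config.luciferase_cv
    for exp in range(1, config.n_luciferase_experiments + 1):
        for construct, effect in config.luciferase_effects.items():
            firefly = tuple(
                float(1e5 * effect * np.exp(rng.normal(0.0, cv))) for _ in range(3)
            )
            renilla = tuple(
                float(1e4 * np.exp(rng.normal(0.0, cv))) for _ in range(3)
            )
            plates.append(LuciferasePlate(construct, firefly, renilla, exp))
    return plates


# ---------------------------------------------------------------------------
# orchestrator
# ---------------------------------------------------------------------------

@dataclass
class SimulatedData:
    config: SimulationConfig
    genome: GenomeTable
    te_copies: list[TECopy]
    peak_sets: dict[str, list[GenomicInterval]]
    tracks: dict[str, tuple[list[TagTrack], TagTrack]]  # mark -> (replicates, control)
    totals: dict[str, int]
    transcripts: dict[str, list[TranscriptModel]]
    cage: list[CageCluster]
    probes: list[ProbeAlignment]
    methylation: pd.DataFrame
    dnase: pd.DataFrame
    luciferase: list[LuciferasePlate]
    truth: GroundTruth


def simulate_all(config: SimulationConfig) -> SimulatedData:
    """Run every generator stage with a shared seed tree and merged outputs."""
    rng_genome, rng_peaks, rng_tags, rng_tx, rng_counts, rng_luc = _rngs(config)
    genome, te_copies = simulate_genome(config, rng_genome)

    zone = config.construct_zone_length()
    exclusion = [
        GenomicInterval(chrom, max(0, L - zone - 400), L)
        for chrom, L in genome.items()
        if zone > 0
    ]
    peak_sets, bg = simulate_peaks(config, genome, te_copies, rng_peaks, exclusion)

    tx = simulate_transcriptome(config, genome, te_copies, rng_tx)
    te_all = sorted(
        te_copies + tx.extra_te, key=lambda c: (c.interval.chrom, c.interval.start)
    )
    if tx.extra_peaks:
        first_tf = config.tfs[0]
        peak_sets[first_tf] = peak_sets[first_tf] + tx.extra_peaks

    # bound copies of the profile subfamily get the elevated tag rate
    members = [c for c in te_all if c.te_subfamily == config.profile_subfamily]
    all_peaks = [p for peaks in peak_sets.values() for p in peaks]
    hit = {si for _, si in intersect(all_peaks, [c.interval for c in members])}
    bound = [c for i, c in enumerate(members) if i in hit]

    tracks: dict[str, tuple[list[TagTrack], TagTrack]] = {}
    totals: dict[str, int] = {}
    for mark in config.marks:
        reps, ctrl, tot = simulate_tags(config, genome, bound, mark, rng_tags)
        tracks[mark] = (reps, ctrl)
        totals.update({f"{mark}:{k}" if k == "input" else k: v
                       for k, v in tot.items()})

    methylation, dnase = simulate_paired_counts(config, rng_counts)
    plates = simulate_luciferase(config, rng_luc)

    truth = GroundTruth(
        planted_enrichment=dict(config.planted_enrichment),
        background_overlap_prob=bg,
        bound_copy_names=[
            f"{c.interval.chrom}:{c.interval.start}-{c.interval.end}" for c in bound
        ],
        bound_fold=config.bound_fold,
        probe_tiers=tx.probe_tiers,
        positives=tx.positives,
        decoys=tx.decoys,
        methylation_delta=config.methylation_delta,
        methylation_sd=config.methylation_sd,
        dnase_p=config.dnase_p,
        luciferase_effects=dict(config.luciferase_effects),
    )
    return SimulatedData(
        config=config, genome=genome, te_copies=te_all, peak_sets=peak_sets,
        tracks=tracks, totals=totals, transcripts=tx.transcripts, cage=tx.cage,
        probes=tx.probes, methylation=methylation, dnase=dnase,
        luciferase=plates, truth=truth,
    )


def write_all(sim: SimulatedData, out_dir: str | Path) -> None:
    """Emit the full synthetic file tree (chrom.sizes, te_table.tsv, peak and
    tag BEDs, totals, BED12 tiers, cage.bed, probes.bed, count TSVs,
    luciferase.tsv, truth.json)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim.genome.write(out / "chrom.sizes")
    write_te_table(out / "te_table.tsv", sim.te_copies)
    for tf, peaks in sim.peak_sets.items():
        write_bed(out / f"peaks_{tf}.bed", peaks)
    for mark, (reps, ctrl) in sim.tracks.items():
        for track in reps:
            write_bed(out / f"tags_{track.label}.bed", track.tags)
        write_bed(out / f"tags_{mark}_input.bed", ctrl.tags)
    with open(out / "totals.tsv", "w") as fh:
        fh.write("#label\ttotal_mapped\n")
        for label, n in sorted(sim.totals.items()):
            fh.write(f"{label}\t{n}\n")
    for i, tier in enumerate(["mRNA", "lncRNA_tier1", "lncRNA_tier2"]):
        write_bed12(out / f"transcripts_tier{i}.bed12", sim.transcripts[tier])
    write_bed(out / "cage.bed",
              [GenomicInterval(c.interval.chrom, c.interval.start, c.interval.end,
                               c.interval.strand, c.cluster_id) for c in sim.cage])
    write_bed(out / "probes.bed",
              [GenomicInterval(p.interval.chrom, p.interval.start, p.interval.end,
                               p.interval.strand, p.probe_id) for p in sim.probes])
    sim.methylation.to_csv(out / "methylation_counts.tsv", sep="\t", index=False)
    sim.dnase.to_csv(out / "dnase_counts.tsv", sep="\t", index=False)
    with open(out / "luciferase.tsv", "w") as fh:
        fh.write("experiment\tconstruct\twell\tfirefly\trenilla\n")
        for p in sim.luciferase:
            for w, (f, r) in enumerate(zip(p.firefly, p.renilla), start=1):
                fh.write(f"{p.experiment}\t{p.construct}\t{w}\t{f:.6f}\t{r:.6f}\n")
    sim.truth.to_json(out / "truth.json")
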