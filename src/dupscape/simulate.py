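"""Synthetic study generator: every pipeline input with known ground truth.

Emulates the study design the pipeline was built for: a multi-chromosome
genome with gene models (CDS/intron/UTR structure), a truth set of tandem
duplications segregating in two butterfly-like species sampled at three
locations (20 + 14 individuals), per-caller noisy re-detections of the truth
events with method-specific breakpoint error, split long reads spanning the
true tandem junctions, and per-sample genotyping evidence tables.

Defaults mirror the study conditions: locus sizes log-normal around a
5,693 bp median spanning 228 bp – 207,510 bp; caller breakpoint jitter well
inside each method's published confidence-interval resolution (PE+SR
50/100 bp, read depth 1 kb/400 bp, split read +/-10 bp); per-method
false-negative and single-method false-positive rates of 5%; a handful of
loci near-fixed in one species and absent in the other (the divergent-
selection pattern); and rare high-copy loci whose read support exceeds the
500-read genotyping filter.

Every generator is a pure function of the config seed: fixed seed implies
byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .calls import DupLocus, PE_SR, RD, SR, METHODS, RawCall
from .features import AnnotationSet, Gene, random_placement
from .genome import GenomeIndex
from .genotyping import SampleMeta
from .longread import Segment, SplitReadAlignment
from . import consensus as _consensus

#: sampling locations with their (lat, lon) covariates
LOCATIONS = {
    "CostaRica": (9.7489, 83.7534),
    "Panama": (8.5380, 80.7821),
    "FrenchGuiana": (3.9339, 53.1258),
}


@dataclass
class SimConfig:
    """Parameters of the synthetic study (defaults = the study conditions)."""

    seed: int = 0

    # genome
    n_chromosomes: int = 21
    mean_chrom_length: int = 13_000_000
    chrom_length_cv: float = 0.15

    # annotation
    gene_density: float = 0.30          # fraction of genome bp inside genes
    mean_exons_per_gene: float = 4.0
    cds_exon_length: int = 300
    intron_length: int = 800
    utr_length: int = 200

    # truth duplications
    n_loci: int = 744
    size_log_median: float = 5693.0
    size_sigma: float = 1.1
    size_min: int = 228
    size_max: int = 207_510

    # samples: species tag -> list of (location, n)
    species_a: str = "melpomene"
    species_b: str = "cydno"
    samples_a: Tuple[Tuple[str, int], ...] = (
        ("CostaRica", 10), ("Panama", 5), ("FrenchGuiana", 5),
    )
    samples_b: Tuple[Tuple[str, int], ...] = (("CostaRica", 10), ("Panama", 4))
    focal_location: str = "CostaRica"

    # frequency spectrum & divergence
    location_effect: float = 0.15       # per-location logistic perturbation
    n_divergent: int = 4
    divergent_high: float = 0.96        # carrier frequency in species B
    divergent_low: float = 0.0          # carrier frequency in species A

    # genotyping evidence
    support_mean: float = 8.0           # mean supporting pairs when present
    genotype_noise: float = 0.01        # per-cell flip rate across threshold
    missing_rate: float = 0.01          # per-cell missing-evidence rate
    high_support_rate: float = 0.02     # high-copy loci (median support > 500)

    # caller emulation
    jitter_sd: Dict[str, float] = field(
        default_factory=lambda: {PE_SR: 15.0, SR: 3.0, RD: 100.0}
    )
    fn_rate: Dict[str, float] = field(
        default_factory=lambda: {PE_SR: 0.05, SR: 0.05, RD: 0.05}
    )
    fp_rate: float = 0.05               # single-method false positives
    low_support_rate: float = 0.02      # PE_SR calls failing the support filter
    ubiquitous_rate: float = 0.01       # reference-artifact loci (all samples)

    # long reads
    junction_coverage: float = 0.95     # per-locus probability of >=1 split read
    reads_per_junction: int = 2
    read_margin: int = 500

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic substream per generator stage."""
        return np.random.default_rng([self.seed, stream])

    def sample_metadata(self) -> List[SampleMeta]:
        out = []
        for species, plan, prefix in (
            (self.species_a, self.samples_a, self.species_a[:3]),
            (self.species_b, self.samples_b, self.species_b[:3]),
        ):
            for location, n in plan:
                lat, lon = LOCATIONS.get(location, (float("nan"), float("nan")))
                for i in range(1, n + 1):
                    out.append(
                        SampleMeta(
                            id=f"{prefix}_{location}_{i:02d}",
                            species=species, location=location, lat=lat, lon=lon,
                        )
                    )
        return out

    def focal_samples(self, species: str) -> List[str]:
        return [
            s.id for s in self.sample_metadata()
            if s.species == species and s.location == self.focal_location
        ]


@dataclass
class TruthSet:
    """Ground-truth duplications and per-sample presence."""

    loci: List[DupLocus]
    presence: pd.DataFrame            # loci x samples, 0/1
    samples: List[SampleMeta]
    divergent_ids: Tuple[str, ...] = ()
    high_support_ids: Tuple[str, ...] = ()
    artifact_loci: List[DupLocus] = field(default_factory=list)

    def locus(self, locus_id: str) -> DupLocus:
        for l in self.loci:
            if l.id == locus_id:
                return l
        raise KeyError(locus_id)

    def discoverable_ids(self, sample_ids: Sequence[str]) -> List[str]:
        """Truth loci carried by at least one of the given samples."""
        sub = self.presence[list(sample_ids)]
        return list(self.presence.index[(sub == 1).any(axis=1)])


# ---------------------------------------------------------------------------
# genome + annotation


def gen_genome_and_annotation(cfg: SimConfig) -> Tuple[GenomeIndex, AnnotationSet]:
    """Generate the reference coordinate space and non-overlapping gene
    models with CDS/intron/UTR structure at the configured density."""
    rng = cfg.rng(1)
    lengths = np.maximum(
        (cfg.mean_chrom_length
         * np.exp(rng.normal(0.0, cfg.chrom_length_cv, cfg.n_chromosomes))
         ).astype(np.int64),
        200_000,
    )
    genome = GenomeIndex(
        [(f"chr{i + 1:02d}", int(L)) for i, L in enumerate(lengths)]
    )
    if not (0 < cfg.gene_density < 0.95):
        raise ValueError("gene density must be in (0, 0.95)")
    n_exons_mean = max(cfg.mean_exons_per_gene, 1.0)
    mean_gene = (
        2 * cfg.utr_length
        + n_exons_mean * cfg.cds_exon_length
        + (n_exons_mean - 1) * cfg.intron_length
    )
    mean_gap = mean_gene * (1 - cfg.gene_density) / cfg.gene_density
    genes: List[Gene] = []
    gid = 0
    for chrom, clen in genome:
        pos = int(rng.exponential(mean_gap / 2))
        while True:
            n_exons = 1 + int(rng.poisson(max(n_exons_mean - 1, 0.0)))
            utr5 = max(30, int(rng.poisson(cfg.utr_length)))
            utr3 = max(30, int(rng.poisson(cfg.utr_length)))
            exon_lens = np.maximum(60, rng.poisson(cfg.cds_exon_length, n_exons))
            intron_lens = np.maximum(60, rng.poisson(cfg.intron_length, max(n_exons - 1, 0)))
            span = utr5 + utr3 + int(exon_lens.sum()) + int(intron_lens.sum())
            if pos + span > clen:
                break
            gid += 1
            start = pos
            cds, exon_blocks = [], []
            cursor = start + utr5
            for i in range(n_exons):
                cds.append((cursor, cursor + int(exon_lens[i])))
                cursor += int(exon_lens[i])
                if i < n_exons - 1:
                    cursor += int(intron_lens[i])
            end = cursor + utr3
            utr = ((start, start + utr5), (end - utr3, end))
            # exon blocks = UTRs fused to their flanking CDS exons
            if n_exons == 1:
                exon_blocks = [(start, end)]
            else:
                exon_blocks = [(start, cds[0][1])]
                exon_blocks += [cds[i] for i in range(1, n_exons - 1)]
                exon_blocks += [(cds[-1][0], end)]
            genes.append(
                Gene(
                    id=f"g{gid:05d}", chrom=chrom, start=start, end=end,
                    cds=tuple(cds), utr=utr, exons=tuple(exon_blocks),
                )
            )
            pos = end + int(rng.exponential(mean_gap))
    if cfg.gene_density > 0 and not genes:
        raise RuntimeError("gene density too high to place any gene")
    return genome, AnnotationSet(genes)


# ---------------------------------------------------------------------------
# truth loci + genotyping evidence


def _draw_sizes(cfg: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    mu = np.log(cfg.size_log_median)
    sizes = np.empty(n, dtype=np.int64)
    for i in range(n):
        for _ in range(100):
            s = int(np.exp(rng.normal(mu, cfg.size_sigma)))
            if cfg.size_min <= s <= cfg.size_max:
                sizes[i] = s
                break
        else:
            sizes[i] = int(np.clip(s, cfg.size_min, cfg.size_max))
    return sizes


def gen_truth_and_genotypes(
    cfg: SimConfig, genome: GenomeIndex
) -> Tuple[TruthSet, pd.DataFrame]:
    """Place truth duplications, draw per-sample presence from a 1/i
    frequency spectrum with per-location perturbations and planted divergent
    loci, and emit the long-format genotyping evidence table."""
    rng = cfg.rng(2)
    samples = cfg.sample_metadata()
    sample_ids = [s.id for s in samples]
    n_tot = len(samples)

    sizes = _draw_sizes(cfg, rng, cfg.n_loci)
    placed = random_placement(sizes, genome, rng)
    locus_ids = [f"T{i + 1:05d}" for i in range(len(placed))]

    # neutral frequency spectrum: carrier count i in 1..n with weight 1/i
    counts = np.arange(1, n_tot + 1)
    weights = (1.0 / counts) / (1.0 / counts).sum()
    base_p = rng.choice(counts, size=cfg.n_loci, p=weights) / n_tot

    divergent = sorted(
        rng.choice(cfg.n_loci, size=min(cfg.n_divergent, cfg.n_loci), replace=False)
    )
    divergent_set = set(int(i) for i in divergent)
    high_support = set(
        int(i) for i in np.flatnonzero(rng.random(cfg.n_loci) < cfg.high_support_rate)
    )

    locations = sorted({s.location for s in samples})
    species = [cfg.species_a, cfg.species_b]
    presence = np.zeros((cfg.n_loci, n_tot), dtype=np.int64)
    for li in range(cfg.n_loci):
        if li in divergent_set:
            p_by_group = {
                (cfg.species_a, loc): cfg.divergent_low for loc in locations
            }
            p_by_group.update(
                {(cfg.species_b, loc): cfg.divergent_high for loc in locations}
            )
        else:
            p = base_p[li]
            p_by_group = {}
            for sp in species:
                for loc in locations:
                    shift = cfg.location_effect * rng.normal()
                    p_by_group[(sp, loc)] = float(np.clip(p * np.exp(shift), 0.0, 1.0))
        row = np.array(
            [rng.random() < p_by_group[(s.species, s.location)] for s in samples],
            dtype=np.int64,
        )
        if row.sum() == 0 and li not in divergent_set:
            row[rng.integers(0, n_tot)] = 1  # a truth locus must have a carrier
        presence[li] = row

    presence_df = pd.DataFrame(presence, index=locus_ids, columns=sample_ids)

    loci = []
    for (chrom, start, end), lid in zip(placed, locus_ids):
        carriers = presence_df.loc[lid]
        sp_tags = frozenset(
            s.species for s in samples if carriers[s.id] == 1
        )
        loci.append(
            DupLocus(chrom=chrom, start=start, end=end, id=lid,
                     species=sp_tags, members=(lid,))
        )

    # evidence: supporting read pairs per locus x sample
    rows = []
    lam_present = max(cfg.support_mean - 3.0, 0.5)
    for li, lid in enumerate(locus_ids):
        for si, sid in enumerate(sample_ids):
            if rng.random() < cfg.missing_rate:
                continue
            present = presence[li, si] == 1
            if rng.random() < cfg.genotype_noise:
                present = not present
            if present:
                pairs = 3 + int(rng.poisson(lam_present))
            else:
                pairs = min(int(rng.poisson(0.3)), 2)
            if li in high_support:
                pairs += 600  # high-copy repeat: reads pile up in every sample
            rows.append((lid, sid, pairs))
    evidence = pd.DataFrame(rows, columns=["locus", "sample", "supporting_pairs"])

    truth = TruthSet(
        loci=loci,
        presence=presence_df,
        samples=samples,
        divergent_ids=tuple(locus_ids[i] for i in divergent),
        high_support_ids=tuple(sorted(locus_ids[i] for i in high_support)),
    )
    return truth, evidence


# ---------------------------------------------------------------------------
# caller emulation


def _jitter_interval(
    rng: np.random.Generator, chrom_len: int, start: int, end: int, sd: float
) -> Tuple[int, int]:
    js = start + int(round(rng.normal(0.0, sd)))
    je = end + int(round(rng.normal(0.0, sd)))
    js = max(0, min(js, chrom_len - 2))
    je = max(js + 1, min(je, chrom_len))
    return js, je


def gen_caller_calls(
    cfg: SimConfig,
    truth: TruthSet,
    genome: GenomeIndex,
    species: str,
) -> Dict[str, List[RawCall]]:
    """Emulate the three caller archetypes for one species' focal samples.

    Each truth locus carried by a focal sample is re-emitted per method with
    Gaussian breakpoint jitter at the method's scale, dropped at the method
    false-negative rate; false positives are added as single-method,
    single-sample calls at random locations; reference-artifact loci are
    emitted by the PE_SR caller in every focal sample.
    """
    rng = cfg.rng(3 if species == cfg.species_a else 4)
    focal = cfg.focal_samples(species)
    out: Dict[str, List[RawCall]] = {m: [] for m in METHODS}
    counter = 0
    for locus in truth.loci:
        carriers = [
            sid for sid in focal if truth.presence.loc[locus.id, sid] == 1
        ]
        if not carriers:
            continue
        clen = genome.length(locus.chrom)
        for method in METHODS:
            sd = cfg.jitter_sd[method]
            fn = cfg.fn_rate[method]
            for sid in carriers:
                if rng.random() < fn:
                    continue
                start, end = _jitter_interval(rng, clen, locus.start, locus.end, sd)
                counter += 1
                support_pairs = support_mq = None
                if method == PE_SR:
                    if rng.random() < cfg.low_support_rate:
                        support_pairs = int(rng.integers(1, 3))
                        support_mq = int(rng.integers(5, 21))
                    else:
                        support_pairs = 3 + int(rng.poisson(5))
                        support_mq = int(rng.integers(30, 61))
                out[method].append(
                    RawCall(
                        chrom=locus.chrom, start=start, end=end, method=method,
                        sample=sid, support_pairs=support_pairs,
                        support_mq=support_mq,
                        id=f"{species}_{method}_c{counter:06d}",
                    )
                )

    # single-method false positives at random genome locations
    n_true = sum(len(v) for v in out.values())
    n_fp = int(rng.binomial(max(n_true, 1), cfg.fp_rate / 3.0))
    for method in METHODS:
        sizes = _draw_sizes(cfg, rng, n_fp)
        for size in sizes:
            chrom = genome.names[int(rng.integers(0, len(genome)))]
            clen = genome.length(chrom)
            if size >= clen:
                continue
            start = int(rng.integers(0, clen - size))
            counter += 1
            sp = sm = None
            if method == PE_SR:
                sp, sm = 3 + int(rng.poisson(5)), int(rng.integers(30, 61))
            out[method].append(
                RawCall(
                    chrom=chrom, start=start, end=start + int(size), method=method,
                    sample=focal[int(rng.integers(0, len(focal)))],
                    support_pairs=sp, support_mq=sm,
                    id=f"{species}_{method}_fp{counter:06d}",
                )
            )

    # reference-artifact loci: reference deletions / assembly errors look
    # like duplications in *every* sample; emitted with PE+SR signal in all
    # focal samples (removable only by the ubiquitous-locus filter, not by
    # the two-method consensus rule)
    n_art = int(round(cfg.ubiquitous_rate * cfg.n_loci))
    if n_art:
        art_sizes = _draw_sizes(cfg, rng, n_art)
        art_placed = random_placement(art_sizes, genome, rng)
        artifacts = []
        for ai, (chrom, start, end) in enumerate(art_placed, 1):
            artifacts.append(
                DupLocus(chrom=chrom, start=start, end=end,
                         id=f"{species}_ART{ai:04d}", members=(f"{species}_ART{ai:04d}",))
            )
            for method in (PE_SR, SR):
                for sid in focal:
                    counter += 1
                    js, je = _jitter_interval(
                        rng, genome.length(chrom), start, end, cfg.jitter_sd[method]
                    )
                    sp = sm = None
                    if method == PE_SR:
                        sp, sm = 3 + int(rng.poisson(5)), int(rng.integers(30, 61))
                    out[method].append(
                        RawCall(
                            chrom=chrom, start=js, end=je, method=method, sample=sid,
                            support_pairs=sp, support_mq=sm,
                            id=f"{species}_{method}_a{counter:06d}",
                        )
                    )
        truth.artifact_loci.extend(artifacts)
    return out


# ---------------------------------------------------------------------------
# split long reads


def gen_split_reads(
    cfg: SimConfig, truth: TruthSet, genome: GenomeIndex
) -> List[SplitReadAlignment]:
    """Simulate split long-read alignments over true tandem junctions.

    Each truth locus is covered with probability ``junction_coverage``; a
    covered locus gets ``reads_per_junction`` reads, the first with the R1
    geometry (two segments aligned to overlapping reference sections,
    spanning the whole duplication) and subsequent ones alternating R2
    (back-jump split). Uncovered loci get no reads.
    """
    rng = cfg.rng(5)
    reads: List[SplitReadAlignment] = []
    for locus in truth.loci:
        if rng.random() >= cfg.junction_coverage:
            continue
        clen = genome.length(locus.chrom)
        s, e = locus.start, locus.end
        L = e - s
        for k in range(cfg.reads_per_junction):
            margin1 = cfg.read_margin + int(rng.integers(0, 200))
            margin2 = cfg.read_margin + int(rng.integers(0, 200))
            rid = f"lr_{locus.id}_{k + 1}"
            if k % 2 == 0:  # R1: overlapping segments spanning the locus
                a = Segment(
                    chrom=locus.chrom, ref_start=max(0, s - margin1), ref_end=e,
                    read_start=0, read_end=e - max(0, s - margin1),
                )
                b_start = a.read_end
                b = Segment(
                    chrom=locus.chrom, ref_start=s, ref_end=min(clen, e + margin2),
                    read_start=b_start, read_end=b_start + min(clen, e + margin2) - s,
                )
            else:  # R2: later segment jumps back upstream
                x = s + max(1, int(0.6 * L))
                y = s + max(1, int(0.4 * L))
                x = min(x, e - 1)
                y = min(y, x)
                a = Segment(
                    chrom=locus.chrom, ref_start=x, ref_end=e,
                    read_start=0, read_end=e - x,
                )
                b = Segment(
                    chrom=locus.chrom, ref_start=s, ref_end=s + max(y - s, 1),
                    read_start=e - x, read_end=e - x + max(y - s, 1),
                )
            reads.append(SplitReadAlignment(read_id=rid, segments=(a, b)))
    return reads


# ---------------------------------------------------------------------------
# calibration fixture for the placement-null significance test


def gen_calibration_fixture(
    chrom_length: int = 900_000, n_chromosomes: int = 2, gap: int = 2000
) -> Tuple[GenomeIndex, AnnotationSet]:
    """Small dense annotation for calibrating the feature-overlap test.

    Three gene archetypes cycle along each chromosome — tiny single-exon
    genes (easily contained by a duplication), long-UTR genes, and
    intron-rich genes — so that every overlap category (complete gene, gene,
    CDS, intron, UTR) has moderate occupancy and the null count distributions
    are smooth rather than concentrated on a few integers. Deterministic: no
    randomness involved.
    """
    archetypes = (
        ("tiny", 60, 60, (240,), ()),
        ("tiny2", 60, 60, (240,), ()),
        ("longutr", 1500, 1500, (300,), ()),
        ("intronic", 150, 150, (150, 150, 150), (2500, 2500)),
    )
    genes: List[Gene] = []
    gid = 0
    for ci in range(n_chromosomes):
        chrom = f"chr{ci + 1}"
        pos = gap
        while True:
            _, utr5, utr3, cds_lens, intron_lens = archetypes[gid % len(archetypes)]
            span = utr5 + utr3 + sum(cds_lens) + sum(intron_lens)
            if pos + span + gap > chrom_length:
                break
            gid += 1
            start = pos
            cursor = start + utr5
            cds = []
            for i, L in enumerate(cds_lens):
                cds.append((cursor, cursor + L))
                cursor += L
                if i < len(intron_lens):
                    cursor += intron_lens[i]
            end = cursor + utr3
            genes.append(
                Gene(
                    id=f"g{gid:04d}", chrom=chrom, start=start, end=end,
                    cds=tuple(cds), utr=((start, start + utr5), (end - utr3, end)),
                )
            )
            pos = end + gap
    genome = GenomeIndex(
        [(f"chr{i + 1}", chrom_length) for i in range(n_chromosomes)]
    )
    return genome, AnnotationSet(genes)


def gen_calibration_sizes(
    rng: np.random.Generator,
    n: int = 250,
    median: float = 1000.0,
    sigma: float = 1.0,
    lo: int = 150,
    hi: int = 12_000,
) -> np.ndarray:
    """Locus sizes for the calibration fixture: log-normal, clipped."""
    return np.clip(
        np.exp(rng.normal(np.log(median), sigma, n)).astype(np.int64), lo, hi
    )


def gen_intergenic_loci(
    ann: AnnotationSet,
    genome: GenomeIndex,
    rng: np.random.Generator,
    n: int = 60,
    size: int = 300,
    max_tries: int = 10000,
) -> List[Tuple[str, int, int]]:
    """Place fixed-size loci entirely outside gene spans (a planted
    gene-depletion signal for the overlap test)."""
    out: List[Tuple[str, int, int]] = []
    for _ in range(n):
        for _ in range(max_tries):
            (placed,) = random_placement([size], genome, rng)
            chrom, s, e = placed
            hit = ann.overlaps_any(
                "gene", chrom, np.array([s], dtype=np.int64), np.array([e], dtype=np.int64)
            )[0]
            if not hit:
                out.append(placed)
                break
        else:
            raise RuntimeError("no intergenic space left")
    return out


# ---------------------------------------------------------------------------
# discovery evaluation


def evaluate_discovery(
    truth_loci: Sequence[DupLocus],
    discovered: Sequence[DupLocus],
    min_overlap: float = 0.9,
) -> Dict[str, float]:
    """Sensitivity/precision of a Discovery Set against truth loci at a
    reciprocal-overlap threshold."""
    matched_truth = set()
    matched_disc = 0
    for d in discovered:
        best, best_ro = None, 0.0
        for t in truth_loci:
            ro = _consensus.reciprocal_overlap(d, t)
            if ro > best_ro:
                best, best_ro = t, ro
        if best is not None and best_ro >= min_overlap:
            matched_disc += 1
            matched_truth.add(best.id)
    sens = len(matched_truth) / len(truth_loci) if truth_loci else float("nan")
    prec = matched_disc / len(discovered) if discovered else float("nan")
    return {
        "sensitivity": sens,
        "precision": prec,
        "n_truth": len(truth_loci),
        "n_discovered": len(discovered),
    }


# ---------------------------------------------------------------------------
# one-call simulation bundle + file output


@dataclass
class SimulatedData:
    config: SimConfig
    genome: GenomeIndex
    annotation: AnnotationSet
    truth: TruthSet
    evidence: pd.DataFrame
    calls: Dict[str, Dict[str, List[RawCall]]]  # species -> method -> calls
    split_reads: List[SplitReadAlignment]


def simulate_all(cfg: SimConfig, out_dir: Optional[Path] = None) -> SimulatedData:
    """Run every generator off one seed; optionally write all input files."""
    genome, ann = gen_genome_and_annotation(cfg)
    truth, evidence = gen_truth_and_genotypes(cfg, genome)
    calls = {
        sp: gen_caller_calls(cfg, truth, genome, sp)
        for sp in (cfg.species_a, cfg.species_b)
    }
    reads = gen_split_reads(cfg, truth, genome)
    data = SimulatedData(
        config=cfg, genome=genome, annotation=ann, truth=truth,
        evidence=evidence, calls=calls, split_reads=reads,
    )
    if out_dir is not None:
        write_simulated_data(data, Path(out_dir))
    return data


def write_simulated_data(data: SimulatedData, out_dir: Path) -> None:
    from . import io as _io
    from .genotyping import write_sample_metadata

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data.genome.to_tsv(out_dir / "genome.sizes.tsv")
    data.annotation.to_gff3(out_dir / "annotation.gff3")
    write_sample_metadata(data.truth.samples, out_dir / "samples.tsv")
    data.evidence.sort_values(["locus", "sample"]).to_csv(
        out_dir / "evidence.tsv", sep="\t", index=False
    )
    for sp, by_method in data.calls.items():
        for method, calls in by_method.items():
            _io.write_calls_tsv(calls, out_dir / f"calls.{sp}.{method}.tsv")
            _io.write_calls_vcf(
                calls, data.genome, out_dir / f"calls.{sp}.{method}.vcf"
            )
    _io.write_bedpe(data.split_reads, out_dir / "splits.bedpe")
    truth_records = {
        "loci": [
            {
                "id": l.id, "chrom": l.chrom, "start": l.start, "end": l.end,
                "species": sorted(l.species),
            }
            for l in data.truth.loci
        ],
        "divergent": list(data.truth.divergent_ids),
        "high_support": list(data.truth.high_support_ids),
        "presence": {
            lid: [int(v) for v in data.truth.presence.loc[lid]]
            for lid in data.truth.presence.index
        },
        "samples": [s.id for s in data.truth.samples],
    }
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth_records, fh, indent=1, sort_keys=True)
        fh.write("\n")
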