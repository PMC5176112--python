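"""Genomic-feature overlap of duplications and a randomized-placement null.

Duplications are classified against gene annotation with a fixed precedence:
any overlap with coding sequence counts as a CDS duplication; otherwise
intron overlap counts as intronic; otherwise UTR overlap as UTR (the
intron/UTR order can be swapped via ``utr_first`` — the annotation wording
leaves that tie ambiguous). Overlap with any of the three is a
gene-overlapping duplication, and a duplication that contains a full gene
span additionally counts as a complete-gene duplication. Overlapping
duplication intervals are merged before this analysis.

Significance is assessed against a permutation null: the same interval sizes
are randomly placed into non-overlapping genome locations many times
(default 10 000) and the 2.5% / 97.5% quantiles of the per-category null
counts serve as critical values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genome import GenomeIndex

CATEGORIES = ("complete_gene", "gene", "CDS", "intron", "UTR")

Interval = Tuple[str, int, int]


# ---------------------------------------------------------------------------
# interval algebra (0-based half-open)


def merge_union(intervals: Iterable[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Union of intervals as maximal disjoint intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    out: List[Tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract(spans: Sequence[Tuple[int, int]], cut: Sequence[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Set difference spans \\ cut, both unions of intervals."""
    cut = merge_union(cut)
    out: List[Tuple[int, int]] = []
    for s, e in merge_union(spans):
        pos = s
        for cs, ce in cut:
            if ce <= pos or cs >= e:
                continue
            if cs > pos:
                out.append((pos, cs))
            pos = max(pos, ce)
            if pos >= e:
                break
        if pos < e:
            out.append((pos, e))
    return out


def flatten_intervals(loci: Sequence) -> List[Interval]:
    """Merge (possibly overlapping) duplication loci into maximal disjoint
    intervals, per chromosome."""
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for l in loci:
        chrom, start, end = _interval_of(l)
        by_chrom.setdefault(chrom, []).append((start, end))
    out: List[Interval] = []
    for chrom in sorted(by_chrom):
        out.extend((chrom, s, e) for s, e in merge_union(by_chrom[chrom]))
    return out


def _interval_of(x) -> Interval:
    if hasattr(x, "chrom"):
        return (x.chrom, x.start, x.end)
    return (x[0], int(x[1]), int(x[2]))


# ---------------------------------------------------------------------------
# annotation


@dataclass(frozen=True)
class Gene:
    """A gene model: span plus child CDS/UTR (and optionally exon) intervals,
    all 0-based half-open on the gene's chromosome."""

    id: str
    chrom: str
    start: int
    end: int
    cds: Tuple[Tuple[int, int], ...] = ()
    utr: Tuple[Tuple[int, int], ...] = ()
    exons: Tuple[Tuple[int, int], ...] = ()

    def __post_init__(self):
        for s, e in (*self.cds, *self.utr, *self.exons):
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"gene {self.id}: child interval outside span")

    @property
    def introns(self) -> Tuple[Tuple[int, int], ...]:
        """Gene span minus CDS, UTR and exonic parts."""
        covered = list(self.cds) + list(self.utr) + list(self.exons)
        return tuple(subtract([(self.start, self.end)], covered))


class AnnotationSet:
    """Gene annotation with fast per-category overlap lookup.

    Categories (gene span, CDS, intron, UTR) are flattened to disjoint
    sorted interval arrays per chromosome; overlap-any and
    contains-a-full-gene queries are O(log n) searchsorted probes.
    """

    def __init__(self, genes: Sequence[Gene]):
        self.genes = sorted(genes, key=lambda g: (g.chrom, g.start, g.end, g.id))
        self._cat: Dict[str, Dict[str, Tuple[np.ndarray, np.ndarray]]] = {}
        self._gene_idx: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        per_cat: Dict[str, Dict[str, List[Tuple[int, int]]]] = {
            "gene": {}, "CDS": {}, "intron": {}, "UTR": {}
        }
        gene_by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for g in self.genes:
            per_cat["gene"].setdefault(g.chrom, []).append((g.start, g.end))
            per_cat["CDS"].setdefault(g.chrom, []).extend(g.cds)
            per_cat["UTR"].setdefault(g.chrom, []).extend(g.utr)
            per_cat["intron"].setdefault(g.chrom, []).extend(g.introns)
            gene_by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
        for cat, by_chrom in per_cat.items():
            self._cat[cat] = {}
            for chrom, ivs in by_chrom.items():
                merged = merge_union(ivs)
                self._cat[cat][chrom] = (
                    np.array([s for s, _ in merged], dtype=np.int64),
                    np.array([e for _, e in merged], dtype=np.int64),
                )
        for chrom, spans in gene_by_chrom.items():
            spans.sort()
            gs = np.array([s for s, _ in spans], dtype=np.int64)
            ge = np.array([e for _, e in spans], dtype=np.int64)
            # suffix-min of ends: a query [s, e) contains a full gene iff the
            # minimal gene end among genes starting at >= s is <= e
            sufmin = np.minimum.accumulate(ge[::-1])[::-1]
            self._gene_idx[chrom] = (gs, sufmin)

    def __len__(self) -> int:
        return len(self.genes)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return self.genes == other.genes

    # -- vectorised queries --------------------------------------------------

    def overlaps_any(self, category: str, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Boolean array: does each [start, end) overlap any ``category``
        interval on ``chrom``?"""
        idx = self._cat[category].get(chrom)
        if idx is None or len(idx[0]) == 0:
            return np.zeros(len(starts), dtype=bool)
        cat_starts, cat_ends = idx
        k = np.searchsorted(cat_starts, ends, side="left")
        hit = k > 0
        hit[hit] = cat_ends[k[hit] - 1] > starts[hit]
        return hit

    def contains_full_gene(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        idx = self._gene_idx.get(chrom)
        if idx is None:
            return np.zeros(len(starts), dtype=bool)
        gs, sufmin = idx
        i0 = np.searchsorted(gs, starts, side="left")
        ok = i0 < len(gs)
        out = np.zeros(len(starts), dtype=bool)
        out[ok] = sufmin[i0[ok]] <= ends[ok]
        return out

    # -- GFF3 I/O -------------------------------------------------------------

    @classmethod
    def from_gff3(cls, path) -> "AnnotationSet":
        """Read gene models (gene / mRNA / exon / CDS / *_UTR features) from
        a GFF3 file. GFF3 1-based inclusive coordinates are converted to
        0-based half-open."""
        import gffutils

        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
        genes = []
        for g in db.features_of_type("gene"):
            cds, utr, exons = [], [], []
            for child in db.children(g.id):
                iv = (child.start - 1, child.end)
                if child.featuretype == "CDS":
                    cds.append(iv)
                elif child.featuretype in ("five_prime_UTR", "three_prime_UTR", "UTR"):
                    utr.append(iv)
                elif child.featuretype == "exon":
                    exons.append(iv)
            genes.append(
                Gene(
                    id=g.id, chrom=g.seqid, start=g.start - 1, end=g.end,
                    cds=tuple(merge_union(cds)), utr=tuple(merge_union(utr)),
                    exons=tuple(merge_union(exons)),
                )
            )
        return cls(genes)

    def to_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in self.genes:
                fh.write(
                    f"{g.chrom}\tdupscape\tgene\t{g.start + 1}\t{g.end}\t.\t+\t.\tID={g.id}\n"
                )
                mrna = f"{g.id}.t1"
                fh.write(
                    f"{g.chrom}\tdupscape\tmRNA\t{g.start + 1}\t{g.end}\t.\t+\t.\tID={mrna};Parent={g.id}\n"
                )
                for i, (s, e) in enumerate(g.exons, 1):
                    fh.write(
                        f"{g.chrom}\tdupscape\texon\t{s + 1}\t{e}\t.\t+\t.\tID={mrna}.exon{i};Parent={mrna}\n"
                    )
                for i, (s, e) in enumerate(g.utr, 1):
                    kind = "five_prime_UTR" if s == g.start else "three_prime_UTR"
                    fh.write(
                        f"{g.chrom}\tdupscape\t{kind}\t{s + 1}\t{e}\t.\t+\t.\tID={mrna}.utr{i};Parent={mrna}\n"
                    )
                for i, (s, e) in enumerate(g.cds, 1):
                    fh.write(
                        f"{g.chrom}\tdupscape\tCDS\t{s + 1}\t{e}\t.\t+\t0\tID={mrna}.cds{i};Parent={mrna}\n"
                    )


# ---------------------------------------------------------------------------
# classification


def classify_feature_overlap(interval, ann: AnnotationSet, utr_first: bool = False) -> frozenset:
    """Category flags for one duplication interval.

    Exclusive precedence for {CDS, intron, UTR} (CDS first; intron before UTR
    unless ``utr_first``); ``gene`` when any of the three overlaps;
    ``complete_gene`` when the interval contains a full gene span. Empty set
    means intergenic.
    """
    chrom, start, end = _interval_of(interval)
    s = np.array([start], dtype=np.int64)
    e = np.array([end], dtype=np.int64)
    cds = bool(ann.overlaps_any("CDS", chrom, s, e)[0])
    intron = bool(ann.overlaps_any("intron", chrom, s, e)[0])
    utr = bool(ann.overlaps_any("UTR", chrom, s, e)[0])
    gene_span = bool(ann.overlaps_any("gene", chrom, s, e)[0])
    flags = set()
    if cds:
        flags.add("CDS")
    elif utr_first:
        if utr:
            flags.add("UTR")
        elif intron:
            flags.add("intron")
    else:
        if intron:
            flags.add("intron")
        elif utr:
            flags.add("UTR")
    if gene_span:
        flags.add("gene")
    if bool(ann.contains_full_gene(chrom, s, e)[0]):
        flags.add("complete_gene")
    return frozenset(flags)


@dataclass(frozen=True)
class OverlapCounts:
    """Per-category duplication counts (Table-style accounting)."""

    counts: Mapping[str, int]
    n_loci: int

    @property
    def proportions(self) -> Dict[str, float]:
        if self.n_loci == 0:
            return {c: float("nan") for c in CATEGORIES}
        return {c: self.counts[c] / self.n_loci for c in CATEGORIES}


def count_categories(
    intervals: Sequence[Interval], ann: AnnotationSet, utr_first: bool = False
) -> OverlapCounts:
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for iv in intervals:
        chrom, s, e = _interval_of(iv)
        by_chrom.setdefault(chrom, []).append((s, e))
    totals = dict.fromkeys(CATEGORIES, 0)
    n = 0
    for chrom, ivs in by_chrom.items():
        starts = np.array([s for s, _ in ivs], dtype=np.int64)
        ends = np.array([e for _, e in ivs], dtype=np.int64)
        n += len(ivs)
        cds = ann.overlaps_any("CDS", chrom, starts, ends)
        intron = ann.overlaps_any("intron", chrom, starts, ends)
        utr = ann.overlaps_any("UTR", chrom, starts, ends)
        gene = ann.overlaps_any("gene", chrom, starts, ends)
        complete = ann.contains_full_gene(chrom, starts, ends)
        if utr_first:
            utr_x = utr & ~cds
            intron_x = intron & ~cds & ~utr
        else:
            intron_x = intron & ~cds
            utr_x = utr & ~cds & ~intron
        totals["CDS"] += int(cds.sum())
        totals["intron"] += int(intron_x.sum())
        totals["UTR"] += int(utr_x.sum())
        totals["gene"] += int(gene.sum())
        totals["complete_gene"] += int(complete.sum())
    return OverlapCounts(counts=totals, n_loci=n)


# ---------------------------------------------------------------------------
# randomized placement null


def random_placement(
    sizes: Sequence[int],
    genome: GenomeIndex,
    rng: np.random.Generator,
    max_tries: int = 10000,
) -> List[Interval]:
    """Place each input size once at a random non-overlapping genome location.

    Chromosome chosen with probability proportional to its length, start
    uniform over the valid range; overlaps with already-placed intervals are
    rejection-resampled (up to ``max_tries`` per interval). The multiset of
    output sizes equals the input sizes.
    """
    sizes_arr = np.asarray(sorted((int(s) for s in sizes), reverse=True), dtype=np.int64)
    n = len(sizes_arr)
    if n == 0:
        return []
    if int(sizes_arr.sum()) >= genome.total_length:
        raise ValueError("total interval size exceeds genome size")
    names = genome.names
    lengths = np.array([genome.length(c) for c in names], dtype=np.int64)
    cumw = np.cumsum(lengths / lengths.sum())
    if int(sizes_arr.sum()) > 0.3 * genome.total_length:
        # crowded genome: strict largest-first sequential rejection avoids
        # fragmentation dead-ends the batched sampler can talk itself into
        return _place_sequential(sizes_arr, names, lengths, cumw, rng, max_tries)
    chrom_of = np.full(n, -1, dtype=np.int64)
    start_of = np.zeros(n, dtype=np.int64)
    tries = np.zeros(n, dtype=np.int64)
    # flat key = chrom_index * K + start keeps per-chromosome interval
    # arithmetic valid and distinct chromosomes far apart
    K = int(lengths.max()) + 2
    settled_keys = np.empty(0, dtype=np.int64)
    settled_ends = np.empty(0, dtype=np.int64)
    pending = np.arange(n)
    while pending.size:
        tries[pending] += 1
        if int(tries[pending].max()) > max_tries:
            raise RuntimeError(
                f"could not place an interval in {max_tries} tries "
                "(genome too crowded)"
            )
        ci = np.minimum(
            np.searchsorted(cumw, rng.random(pending.size), side="right"),
            len(names) - 1,
        )
        room = lengths[ci] - sizes_arr[pending]
        fits = room >= 0
        # start uniform over [0, chrom_len - size]
        starts = np.floor(rng.random(pending.size) * (room + 1)).astype(np.int64)
        cand = pending[fits]
        cand_key = ci[fits] * K + starts[fits]
        cand_end = cand_key + sizes_arr[cand]
        # phase 1: reject candidates overlapping settled intervals
        if settled_keys.size:
            idx = np.searchsorted(settled_keys, cand_end, side="left")
            clash = idx > 0
            clash[clash] = settled_ends[idx[clash] - 1] > cand_key[clash]
            ok = ~clash
        else:
            ok = np.ones(cand.size, dtype=bool)
        # phase 2: among surviving candidates, keep-first in coordinate order
        surv = np.flatnonzero(ok)
        order = surv[np.argsort(cand_key[surv], kind="stable")]
        covered_end = -1
        for j in order:
            if cand_key[j] >= covered_end:
                covered_end = cand_end[j]
            else:
                ok[j] = False
        acc = cand[ok]
        chrom_of[acc] = ci[fits][ok]
        start_of[acc] = starts[fits][ok]
        merged_keys = np.concatenate([settled_keys, cand_key[ok]])
        merged_ends = np.concatenate([settled_ends, cand_end[ok]])
        o = np.argsort(merged_keys, kind="stable")
        settled_keys, settled_ends = merged_keys[o], merged_ends[o]
        pending = np.concatenate([pending[~fits], cand[~ok]])
    out = [
        (names[int(chrom_of[i])], int(start_of[i]), int(start_of[i] + sizes_arr[i]))
        for i in range(n)
    ]
    out.sort()
    return out


def _place_sequential(
    sizes_arr, names, lengths, cumw, rng: np.random.Generator, max_tries: int
) -> List[Interval]:
    from bisect import bisect_right

    placed_starts: Dict[str, List[int]] = {c: [] for c in names}
    placed_ends: Dict[str, List[int]] = {c: [] for c in names}
    out: List[Interval] = []
    for size in sizes_arr:
        size = int(size)
        for _ in range(max_tries):
            ci = min(
                int(np.searchsorted(cumw, rng.random(), side="right")), len(names) - 1
            )
            clen = int(lengths[ci])
            if size > clen:
                continue
            start = int(np.floor(rng.random() * (clen - size + 1)))
            end = start + size
            ss, ee = placed_starts[names[ci]], placed_ends[names[ci]]
            k = bisect_right(ss, start)
            if (k > 0 and ee[k - 1] > start) or (k < len(ss) and ss[k] < end):
                continue
            ss.insert(k, start)
            ee.insert(k, end)
            out.append((names[ci], start, end))
            break
        else:
            raise RuntimeError(
                f"could not place a {size} bp interval in {max_tries} tries "
                "(genome too crowded)"
            )
    out.sort()
    return out


@dataclass
class PermutationResult:
    """Observed overlap counts with their randomized-placement null."""

    observed: OverlapCounts
    quantiles: Dict[str, Tuple[float, float]]
    significant: Dict[str, Optional[str]]  # None | 'depleted' | 'enriched'
    n_iter: int
    null_counts: Optional[np.ndarray] = None  # n_iter x len(CATEGORIES)

    def summary(self) -> pd.DataFrame:
        rows = []
        for i, cat in enumerate(CATEGORIES):
            lo, hi = self.quantiles[cat]
            rows.append(
                {
                    "category": cat,
                    "observed": self.observed.counts[cat],
                    "proportion": round(self.observed.proportions[cat], 4),
                    "null_q2.5": lo,
                    "null_q97.5": hi,
                    "significant": self.significant[cat] or "No",
                }
            )
        return pd.DataFrame(rows)


def overlap_permutation_test(
    loci: Sequence,
    ann: AnnotationSet,
    genome: GenomeIndex,
    n_iter: int = 10000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    utr_first: bool = False,
    keep_null: bool = False,
) -> PermutationResult:
    """Test observed feature-overlap counts against a randomized-placement
    null: loci are flattened to disjoint intervals, their sizes randomly
    re-placed across the genome ``n_iter`` times, and the 2.5% / 97.5%
    quantiles of the null counts used as two-sided critical values."""
    if n_iter < 100:
        warnings.warn(f"n_iter={n_iter} gives unstable tail quantiles", stacklevel=2)
    if rng is None:
        rng = np.random.default_rng(seed)
    intervals = flatten_intervals(loci)
    observed = count_categories(intervals, ann, utr_first=utr_first)
    sizes = [e - s for _, s, e in intervals]
    null = np.empty((n_iter, len(CATEGORIES)), dtype=np.int64)
    for it in range(n_iter):
        placed = random_placement(sizes, genome, rng)
        cc = count_categories(placed, ann, utr_first=utr_first)
        null[it] = [cc.counts[c] for c in CATEGORIES]
    qlo = np.quantile(null, 0.025, axis=0)
    qhi = np.quantile(null, 0.975, axis=0)
    quantiles, significant = {}, {}
    for i, cat in enumerate(CATEGORIES):
        quantiles[cat] = (float(qlo[i]), float(qhi[i]))
        obs = observed.counts[cat]
        if obs < qlo[i]:
            significant[cat] = "depleted"
        elif obs > qhi[i]:
            significant[cat] = "enriched"
        else:
            significant[cat] = None
    return PermutationResult(
        observed=observed,
        quantiles=quantiles,
        significant=significant,
        n_iter=n_iter,
        null_counts=null if keep_null else None,
    )


# ---------------------------------------------------------------------------
# per-chromosome density


def chromosome_density(loci: Sequence, genome: GenomeIndex) -> Tuple[pd.DataFrame, float]:
    """Per-chromosome duplication counts and densities, plus the squared
    Pearson correlation of count against chromosome length."""
    if len(genome) < 2:
        raise ValueError("need >= 2 chromosomes")
    counts = dict.fromkeys(genome.names, 0)
    for l in loci:
        chrom, _, _ = _interval_of(l)
        if chrom in counts:
            counts[chrom] += 1
    rows = [
        {
            "chrom": name,
            "length": length,
            "count": counts[name],
            "per_mb": counts[name] / (length / 1e6),
        }
        for name, length in genome
    ]
    df = pd.DataFrame(rows)
    c = df["count"].to_numpy(dtype=float)
    l = df["length"].to_numpy(dtype=float)
    if np.std(c) == 0 or np.std(l) == 0:
        # constant counts or constant lengths: correlation undefined
        r2 = float("nan")
    else:
        r2 = float(np.corrcoef(c, l)[0, 1] ** 2)
    return df, r2
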