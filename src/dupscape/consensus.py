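"""Multi-signal consensus merging of duplication calls.

The discovery pipeline turns per-tool raw duplication calls into a
non-redundant per-species Discovery Set:

1. support filtering of PE_SR calls (>= 3 read pairs, mapping quality > 20);
2. per-breakpoint confidence intervals from each method's resolution profile;
3. within-tool merging — calls whose confidence intervals intersect at *both*
   the start and the end breakpoint are combined into a single event;
4. removal of loci predicted in every reference-species sample (likely
   assembly errors or genuine deletions in the reference);
5. cross-tool consensus — events clustered at reciprocal overlap >= 90% and
   kept only when supported by at least two distinct methods.

Two per-species Genotyping Sets are later merged across species at strict
reciprocal overlap > 90% into one combined set.

All clustering is single-linkage (transitive closure of the pairwise link
relation), processed in deterministic coordinate order, and iterated on
cluster representatives until a fixed point so that merging is idempotent.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .calls import (
    CICall,
    DupLocus,
    DEFAULT_PROFILES,
    METHOD_RANK,
    MethodProfile,
    PE_SR,
    RawCall,
)
from .genome import GenomeIndex


# ---------------------------------------------------------------------------
# breakpoint confidence intervals


def assign_breakpoint_ci(
    call: RawCall,
    genome: GenomeIndex,
    profile: Optional[MethodProfile] = None,
    profiles: Mapping[str, MethodProfile] = DEFAULT_PROFILES,
) -> CICall:
    """Attach closed breakpoint confidence intervals to a raw call.

    The start CI extends ``outward`` bp to the left and ``inward`` bp to the
    right of the start breakpoint; the end CI mirrors this (``inward`` left,
    ``outward`` right). Both are clamped to the chromosome bounds.
    """
    if profile is None:
        try:
            profile = profiles[call.method]
        except KeyError:
            raise KeyError(f"no confidence-interval profile for method {call.method!r}") from None
    genome.validate_interval(call.chrom, call.start, call.end)
    clen = genome.length(call.chrom)
    start_ci = (max(0, call.start - profile.outward), min(clen, call.start + profile.inward))
    end_ci = (max(0, call.end - profile.inward), min(clen, call.end + profile.outward))
    return CICall(call=call, start_ci=start_ci, end_ci=end_ci)


# ---------------------------------------------------------------------------
# reciprocal overlap


def reciprocal_overlap(a, b) -> float:
    """Reciprocal overlap of two half-open intervals.

    ``min(overlap/|a|, overlap/|b|)``; 0.0 if disjoint or on different
    chromosomes. Accepts ``(start, end)`` or ``(chrom, start, end)`` tuples,
    or any object with ``chrom``/``start``/``end`` attributes.
    """
    ca, sa, ea = _as_interval(a)
    cb, sb, eb = _as_interval(b)
    if ea <= sa or eb <= sb:
        raise ValueError("zero-length interval")
    if ca is not None and cb is not None and ca != cb:
        return 0.0
    ov = min(ea, eb) - max(sa, sb)
    if ov <= 0:
        return 0.0
    return min(ov / (ea - sa), ov / (eb - sb))


def _as_interval(x) -> Tuple[Optional[str], int, int]:
    if hasattr(x, "start") and hasattr(x, "end"):
        return (getattr(x, "chrom", None), x.start, x.end)
    if len(x) == 3:
        return (x[0], x[1], x[2])
    return (None, x[0], x[1])


# ---------------------------------------------------------------------------
# generic single-linkage clustering (transitive closure of a link relation)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def single_linkage_clusters(items: Sequence, link, lo_key, hi_key) -> List[List]:
    """Cluster ``items`` by the transitive closure of the pairwise ``link``
    relation.

    ``lo_key``/``hi_key`` give, per item, a 1-D pruning window: a pair can
    only link if their windows intersect, which lets the sweep skip distant
    pairs. The result is independent of input order (clusters are returned
    sorted by their minimal ``lo_key``; members keep deterministic order).
    """
    n = len(items)
    order = sorted(range(n), key=lambda i: (lo_key(items[i]), hi_key(items[i])))
    uf = _UnionFind(n)
    for a in range(n):
        i = order[a]
        hi = hi_key(items[i])
        for b in range(a + 1, n):
            j = order[b]
            if lo_key(items[j]) > hi:
                break
            if link(items[i], items[j]):
                uf.union(i, j)
    groups: Dict[int, List] = defaultdict(list)
    for a in range(n):
        i = order[a]
        groups[uf.find(i)].append(items[i])
    clusters = list(groups.values())
    clusters.sort(key=lambda cl: min((lo_key(x), hi_key(x)) for x in cl))
    return clusters


def brute_force_clusters(items: Sequence, link) -> List[frozenset]:
    """All-pairs transitive-closure oracle; for testing only.

    Evaluates ``link`` on every pair, closes the boolean adjacency matrix by
    repeated squaring, and returns the partition of item *indices* as
    frozensets. Independent of the sweep/union-find implementation.
    """
    import numpy as np

    n = len(items)
    adj = np.eye(n, dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            adj[i, j] = adj[j, i] = bool(link(items[i], items[j]))
    while True:
        closed = adj | (adj @ adj)
        if np.array_equal(closed, adj):
            break
        adj = closed
    seen, out = set(), []
    for i in range(n):
        if i in seen:
            continue
        comp = frozenset(np.flatnonzero(adj[i]).tolist())
        seen |= comp
        out.append(comp)
    return out


# ---------------------------------------------------------------------------
# representative coordinates


def _median_coord(values_with_rank: List[Tuple[int, int]]) -> int:
    """Median of member coordinates; for even counts the tie between the two
    middle values is broken toward the finer-resolution method (lower rank),
    then toward the lower coordinate."""
    vs = sorted(values_with_rank)
    n = len(vs)
    if n % 2 == 1:
        return vs[n // 2][0]
    a, b = vs[n // 2 - 1], vs[n // 2]
    if a[1] != b[1]:
        return a[0] if a[1] < b[1] else b[0]
    return a[0]


def _ci_link(x: CICall, y: CICall) -> bool:
    return (
        x.chrom == y.chrom
        and x.start_ci[0] <= y.start_ci[1]
        and y.start_ci[0] <= x.start_ci[1]
        and x.end_ci[0] <= y.end_ci[1]
        and y.end_ci[0] <= x.end_ci[1]
    )


def _cluster_to_locus(members: List[CICall]) -> DupLocus:
    rank = lambda c: METHOD_RANK.get(c.method, 99)
    start = _median_coord([(c.start, rank(c)) for c in members])
    end = _median_coord([(c.end, rank(c)) for c in members])
    if end <= start:  # degenerate median pairing on tiny intervals
        start, end = min(c.start for c in members), max(c.end for c in members)
    member_ids = tuple(
        sorted(c.call.id if c.call.id else f"{c.chrom}:{c.start}-{c.end}:{c.sample}" for c in members)
    )
    return DupLocus(
        chrom=members[0].chrom,
        start=start,
        end=end,
        methods=frozenset(c.method for c in members),
        members=member_ids,
        samples=frozenset(c.sample for c in members),
        start_ci=(min(c.start_ci[0] for c in members), max(c.start_ci[1] for c in members)),
        end_ci=(min(c.end_ci[0] for c in members), max(c.end_ci[1] for c in members)),
    )


def merge_within_tool(calls: Sequence[CICall]) -> List[DupLocus]:
    """Combine calls with intersecting confidence intervals at both the start
    and the end breakpoint into single events (one caller, one species).

    Single-linkage over the pairwise CI-intersection relation, then iterated
    on the merged events' consensus CIs until no two events link, so the
    operation is idempotent. Representative coordinates are the median of
    member starts/ends.
    """
    if not calls:
        return []
    by_chrom: Dict[str, List[CICall]] = defaultdict(list)
    for c in calls:
        by_chrom[c.chrom].append(c)
    loci: List[DupLocus] = []
    for chrom in sorted(by_chrom):
        groups = [[c] for c in by_chrom[chrom]]
        while True:
            reps = [_envelope_call(g) for g in groups]
            clusters = single_linkage_clusters(
                reps, _ci_link, lambda c: c.start_ci[0], lambda c: c.start_ci[1]
            )
            if len(clusters) == len(groups):
                break
            index = {id(r): g for r, g in zip(reps, groups)}
            groups = [[c for rep in cl for c in index[id(rep)]] for cl in clusters]
        loci.extend(_cluster_to_locus(g) for g in groups)
    return _sorted_with_ids(loci)


def _envelope_call(members: List[CICall]) -> CICall:
    """Representative CICall for a group: median coordinates, consensus
    (envelope) confidence intervals."""
    if len(members) == 1:
        return members[0]
    loc = _cluster_to_locus(members)
    base = members[0].call
    rep = RawCall(
        chrom=loc.chrom, start=loc.start, end=loc.end,
        method=base.method, sample=base.sample,
    )
    return CICall(
        call=rep,
        start_ci=(min(loc.start_ci[0], loc.start), max(loc.start_ci[1], loc.start)),
        end_ci=(min(loc.end_ci[0], loc.end), max(loc.end_ci[1], loc.end)),
    )


def _sorted_with_ids(loci: Iterable[DupLocus], prefix: str = "DUP") -> List[DupLocus]:
    out = sorted(loci, key=lambda l: (l.chrom, l.start, l.end))
    return [l.with_id(f"{prefix}{i:06d}") for i, l in enumerate(out, start=1)]


# ---------------------------------------------------------------------------
# call-level filters


def filter_support(
    calls: Sequence[RawCall], min_pairs: int = 3, min_mq: int = 20
) -> List[RawCall]:
    """Keep PE_SR calls with >= ``min_pairs`` supporting read pairs of mapping
    quality strictly greater than ``min_mq``; other methods pass through."""
    out = []
    for c in calls:
        if c.method != PE_SR:
            out.append(c)
            continue
        if c.support_pairs is None or c.support_mq is None:
            raise ValueError(f"PE_SR call {c.chrom}:{c.start}-{c.end} lacks support fields")
        if c.support_pairs >= min_pairs and c.support_mq > min_mq:
            out.append(c)
    return out


def drop_ubiquitous(
    loci: Sequence[DupLocus], reference_species_samples: Sequence[str]
) -> List[DupLocus]:
    """Remove loci predicted in *every* reference-species sample — these are
    likely genome assembly errors or genuine deletions in the reference."""
    ref = set(reference_species_samples)
    if not ref:
        raise ValueError("reference sample list is empty")
    return [l for l in loci if not ref <= l.samples]


# ---------------------------------------------------------------------------
# cross-tool consensus and cross-species merge


def _locus_rank(l: DupLocus) -> int:
    return min((METHOD_RANK.get(m, 99) for m in l.methods), default=99)


def _merge_locus_cluster(members: List[DupLocus], species: Optional[str] = None) -> DupLocus:
    start = _median_coord([(l.start, _locus_rank(l)) for l in members])
    end = _median_coord([(l.end, _locus_rank(l)) for l in members])
    if end <= start:
        start, end = min(l.start for l in members), max(l.end for l in members)
    cis = [l for l in members if l.start_ci is not None and l.end_ci is not None]
    start_ci = end_ci = None
    if cis:
        start_ci = (min(l.start_ci[0] for l in cis), max(l.start_ci[1] for l in cis))
        end_ci = (min(l.end_ci[0] for l in cis), max(l.end_ci[1] for l in cis))
    tags = frozenset().union(*(l.species for l in members))
    if species is not None:
        tags = tags | {species}
    return DupLocus(
        chrom=members[0].chrom,
        start=start,
        end=end,
        methods=frozenset().union(*(l.methods for l in members)),
        members=tuple(sorted(set(m for l in members for m in l.members)
                             or set(l.id for l in members if l.id))),
        samples=frozenset().union(*(l.samples for l in members)),
        species=tags,
        start_ci=start_ci,
        end_ci=end_ci,
    )


def _cluster_loci(
    loci: Sequence[DupLocus], min_overlap: float, strict: bool
) -> List[List[DupLocus]]:
    def link(a: DupLocus, b: DupLocus) -> bool:
        ro = reciprocal_overlap(a, b)
        return ro > min_overlap if strict else ro >= min_overlap

    by_chrom: Dict[str, List[DupLocus]] = defaultdict(list)
    for l in loci:
        by_chrom[l.chrom].append(l)
    out: List[List[DupLocus]] = []
    for chrom in sorted(by_chrom):
        groups = [[l] for l in by_chrom[chrom]]
        while True:
            reps = [g[0] if len(g) == 1 else _merge_locus_cluster(g) for g in groups]
            clusters = single_linkage_clusters(
                reps, link, lambda l: l.start, lambda l: l.end - 1
            )
            if len(clusters) == len(groups):
                break
            index = {id(r): g for r, g in zip(reps, groups)}
            groups = [[l for rep in cl for l in index[id(rep)]] for cl in clusters]
        out.extend(groups)
    return out


def consensus_across_tools(
    per_tool_loci: Mapping[str, Sequence[DupLocus]],
    min_overlap: float = 0.9,
    min_tools: int = 2,
) -> List[DupLocus]:
    """Cluster per-tool merged events at reciprocal overlap >= ``min_overlap``
    and keep clusters supported by at least ``min_tools`` distinct methods."""
    if not (0 < min_overlap <= 1):
        raise ValueError(f"min_overlap must be in (0, 1], got {min_overlap}")
    pooled: List[DupLocus] = []
    for method in sorted(per_tool_loci):
        for l in per_tool_loci[method]:
            pooled.append(
                l if method in l.methods else
                DupLocus(**{**l.__dict__, "methods": l.methods | {method}})
            )
    clusters = _cluster_loci(pooled, min_overlap, strict=False)
    kept = [
        _merge_locus_cluster(cl)
        for cl in clusters
        if len(frozenset().union(*(l.methods for l in cl))) >= min_tools
    ]
    return _sorted_with_ids(kept)


def merge_cross_species(
    set_a: Sequence[DupLocus],
    set_b: Sequence[DupLocus],
    min_overlap: float = 0.9,
    species_a: str = "A",
    species_b: str = "B",
) -> List[DupLocus]:
    """Merge two species-level Genotyping Sets: loci with strict reciprocal
    overlap > ``min_overlap`` collapse into one shared locus tagged with both
    species; all others are retained with their own tag."""
    tagged = [
        DupLocus(**{**l.__dict__, "species": l.species | {tag}})
        for loci, tag in ((set_a, species_a), (set_b, species_b))
        for l in loci
    ]
    clusters = _cluster_loci(tagged, min_overlap, strict=True)
    return _sorted_with_ids([_merge_locus_cluster(cl) for cl in clusters], prefix="HEL")


# ---------------------------------------------------------------------------
# end-to-end discovery pipeline


def discovery_set(
    calls_by_method: Mapping[str, Sequence[RawCall]],
    genome: GenomeIndex,
    profiles: Mapping[str, MethodProfile] = DEFAULT_PROFILES,
    min_pairs: int = 3,
    min_mq: int = 20,
    min_overlap: float = 0.9,
    min_tools: int = 2,
    reference_samples: Optional[Sequence[str]] = None,
) -> List[DupLocus]:
    """Run the full per-species discovery pipeline on raw per-tool calls.

    Support filter (PE_SR) -> per-breakpoint CIs -> within-tool merge ->
    optional ubiquitous-locus removal (PE_SR events present in every
    reference-species sample) -> cross-tool consensus.
    """
    per_tool: Dict[str, List[DupLocus]] = {}
    for method in sorted(calls_by_method):
        calls = list(calls_by_method[method])
        if method == PE_SR:
            calls = filter_support(calls, min_pairs=min_pairs, min_mq=min_mq)
        ci_calls = [assign_breakpoint_ci(c, genome, profiles=profiles) for c in calls]
        loci = merge_within_tool(ci_calls)
        if method == PE_SR and reference_samples:
            loci = drop_ubiquitous(loci, reference_samples)
        per_tool[method] = loci
    return consensus_across_tools(per_tool, min_overlap=min_overlap, min_tools=min_tools)
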