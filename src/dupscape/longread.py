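"""Breakpoint validation of tandem duplications from split long reads.

A tandem duplication produces a characteristic back-to-back junction. When a
long read from a duplicated haplotype is aligned to a non-duplicated
reference, the aligner splits it, leaving one of two signatures:

* **R1** — the read spans the entire duplicated segment twice, so two of its
  segments align to *overlapping* sections of the reference;
* **R2** — the read starts inside the first copy and ends inside the second,
  so a later read segment aligns strictly *upstream* of an earlier segment
  in the reference (a back-jump) without overlap.

Each adjacent split pair is converted into a breakpoint candidate whose two
junction positions are extended by a slope (default 1000 bp). A predicted
duplication is validated when at least one candidate's junction intervals
intersect both of the locus's breakpoint confidence intervals and the source
read carries an R1 or R2 signature. Only same-strand splits are considered
(tandem-duplication geometry implies same orientation); inverted splits are
skipped with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

from .calls import CICall, DupLocus
from .genome import GenomeIndex

R1 = "R1"
R2 = "R2"
NONE = "none"
VALIDATED_R1 = "validated_R1"
VALIDATED_R2 = "validated_R2"
NOT_VALIDATED = "not_validated"


@dataclass(frozen=True)
class Segment:
    """One aligned block of a split read (reference and read coordinates,
    both 0-based half-open)."""

    chrom: str
    ref_start: int
    ref_end: int
    read_start: int
    read_end: int
    strand: str = "+"

    def __post_init__(self):
        if self.ref_end <= self.ref_start or self.read_end <= self.read_start:
            raise ValueError("degenerate segment")

    @property
    def ref_length(self) -> int:
        return self.ref_end - self.ref_start


@dataclass(frozen=True)
class SplitReadAlignment:
    """Ordered aligned segments of one long read.

    Segments are stored sorted by read coordinate; read coordinates must not
    overlap (each read base aligns at most once).
    """

    read_id: str
    segments: Tuple[Segment, ...]

    def __post_init__(self):
        if not self.segments:
            raise ValueError("read with no segments")
        segs = tuple(sorted(self.segments, key=lambda s: s.read_start))
        for a, b in zip(segs, segs[1:]):
            if b.read_start < a.read_end:
                raise ValueError(f"read {self.read_id}: overlapping read coordinates")
        object.__setattr__(self, "segments", segs)


@dataclass(frozen=True)
class BreakpointCandidate:
    """A putative tandem-duplication junction from one adjacent split pair.

    ``left``/``right`` are the two junction positions after normalisation
    (left <= right); ``left_interval``/``right_interval`` are those positions
    extended by +/- slope bp.
    """

    chrom: str
    left: int
    right: int
    left_interval: Tuple[int, int]
    right_interval: Tuple[int, int]
    read_id: str

    def __post_init__(self):
        if self.left > self.right:
            raise ValueError("candidate not normalised (left > right)")


@dataclass(frozen=True)
class ValidationVerdict:
    locus_id: str
    status: str
    reads: Tuple[str, ...] = ()

    def __post_init__(self):
        if self.status in (VALIDATED_R1, VALIDATED_R2) and not self.reads:
            raise ValueError("validated verdict requires >= 1 supporting read")

    @property
    def validated(self) -> bool:
        return self.status in (VALIDATED_R1, VALIDATED_R2)


def _usable_pairs(read: SplitReadAlignment, min_segment_length: int):
    """Adjacent same-chromosome, same-strand segment pairs of sufficient
    length, in read order."""
    segs = [s for s in read.segments if s.ref_length >= min_segment_length]
    for a, b in zip(segs, segs[1:]):
        if a.chrom != b.chrom:
            warnings.warn(
                f"read {read.read_id}: cross-chromosome split skipped "
                "(translocation-like)", stacklevel=2,
            )
            continue
        if a.strand != b.strand:
            warnings.warn(
                f"read {read.read_id}: inverted split skipped", stacklevel=2
            )
            continue
        yield a, b


def split_to_breakpoints(
    reads: Sequence[SplitReadAlignment],
    slope: int = 1000,
    genome: Optional[GenomeIndex] = None,
    min_segment_length: int = 100,
) -> List[BreakpointCandidate]:
    """Convert split alignments into breakpoint candidates.

    For each adjacent segment pair the junction positions are the facing
    segment ends (first segment's reference end, second segment's reference
    start), each extended by +/- ``slope`` bp and clamped to the chromosome
    when a genome index is given. Single-segment reads yield nothing.
    """
    out: List[BreakpointCandidate] = []
    for read in reads:
        for a, b in _usable_pairs(read, min_segment_length):
            j1, j2 = a.ref_end, b.ref_start
            left, right = (j1, j2) if j1 <= j2 else (j2, j1)
            clen = genome.length(a.chrom) if genome is not None else None

            def _win(pos: int) -> Tuple[int, int]:
                lo, hi = pos - slope, pos + slope
                if clen is not None:
                    lo, hi = max(0, lo), min(clen, hi)
                return (lo, hi)

            out.append(
                BreakpointCandidate(
                    chrom=a.chrom, left=left, right=right,
                    left_interval=_win(left), right_interval=_win(right),
                    read_id=read.read_id,
                )
            )
    return out


def classify_read_signature(
    read: SplitReadAlignment, min_segment_length: int = 100
) -> str:
    """Classify a split read by its tandem-duplication junction signature.

    ``R1`` if any adjacent pair aligns to overlapping reference sections;
    otherwise ``R2`` if any later segment aligns strictly upstream of the
    preceding segment's reference interval without overlap; ``none``
    otherwise (ordinary colinear gapped alignment).
    """
    saw_r2 = False
    for a, b in _usable_pairs(read, min_segment_length):
        if b.ref_start < a.ref_end and a.ref_start < b.ref_end:
            return R1
        if b.ref_end <= a.ref_start:
            saw_r2 = True
    return R2 if saw_r2 else NONE


def _locus_cis(
    locus: Union[CICall, DupLocus], slack: Optional[int]
) -> Tuple[Tuple[int, int], Tuple[int, int]]:
    start_ci = getattr(locus, "start_ci", None)
    end_ci = getattr(locus, "end_ci", None)
    if start_ci is None or end_ci is None:
        if slack is None:
            raise ValueError(
                "locus has no breakpoint confidence intervals; pass slack= to "
                "apply a +/- window"
            )
        start_ci = (locus.start - slack, locus.start + slack)
        end_ci = (locus.end - slack, locus.end + slack)
    return start_ci, end_ci


def validate_locus(
    locus: Union[CICall, DupLocus],
    candidates: Sequence[BreakpointCandidate],
    reads: Mapping[str, SplitReadAlignment],
    slack: Optional[int] = None,
    min_segment_length: int = 100,
) -> ValidationVerdict:
    """Validate one predicted duplication against breakpoint candidates.

    The locus is validated when at least one candidate has its lower junction
    interval intersecting the locus start CI *and* its upper junction
    interval intersecting the end CI, and its source read classifies as R1 or
    R2. The verdict records the signature (R1 preferred when both occur).
    """
    start_ci, end_ci = _locus_cis(locus, slack)
    locus_id = getattr(locus, "id", None) or f"{locus.chrom}:{locus.start}-{locus.end}"
    support: Dict[str, List[str]] = {R1: [], R2: []}
    for cand in candidates:
        if cand.chrom != locus.chrom:
            continue
        if not _intersect(cand.left_interval, start_ci):
            continue
        if not _intersect(cand.right_interval, end_ci):
            continue
        read = reads.get(cand.read_id)
        if read is None:
            continue
        sig = classify_read_signature(read, min_segment_length)
        if sig in (R1, R2):
            support[sig].append(cand.read_id)
    if support[R1]:
        return ValidationVerdict(locus_id, VALIDATED_R1, tuple(sorted(set(support[R1]))))
    if support[R2]:
        return ValidationVerdict(locus_id, VALIDATED_R2, tuple(sorted(set(support[R2]))))
    return ValidationVerdict(locus_id, NOT_VALIDATED)


def _intersect(a: Tuple[int, int], b: Tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def validate_loci(
    loci: Sequence[Union[CICall, DupLocus]],
    reads: Sequence[SplitReadAlignment],
    slope: int = 1000,
    slack: Optional[int] = None,
    genome: Optional[GenomeIndex] = None,
    min_segment_length: int = 100,
) -> List[ValidationVerdict]:
    """Validate a set of loci against a set of split reads (convenience
    wrapper: builds candidates once, then judges every locus)."""
    candidates = split_to_breakpoints(
        reads, slope=slope, genome=genome, min_segment_length=min_segment_length
    )
    read_map = {r.read_id: r for r in reads}
    return [
        validate_locus(l, candidates, read_map, slack=slack,
                       min_segment_length=min_segment_length)
        for l in loci
    ]


def validation_rate(verdicts: Sequence[ValidationVerdict]) -> float:
    """Fraction of loci with a validated verdict."""
    if not verdicts:
        raise ValueError("no verdicts")
    return sum(v.validated for v in verdicts) / len(verdicts)
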