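"""Domain records for duplication calls and merged loci.

Three caller archetypes are distinguished by the sequencing signal they use:

* ``PE_SR`` — paired-end plus split-read evidence (DELLY-like),
* ``SR``   — split-read only (Pindel-like),
* ``RD``   — read-depth only (CNVnator-like).

Each archetype has a characteristic breakpoint resolution, encoded as a
:class:`MethodProfile` giving the slack applied outward/inward of each
reported breakpoint when building confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import FrozenSet, Optional, Tuple

PE_SR = "PE_SR"
SR = "SR"
RD = "RD"
METHODS = (PE_SR, SR, RD)

#: Breakpoint resolution rank used for deterministic tie-breaking when picking
#: representative coordinates of a merged cluster (lower = finer resolution).
METHOD_RANK = {SR: 0, PE_SR: 1, RD: 2}


@dataclass(frozen=True)
class MethodProfile:
    """Breakpoint confidence-interval slack for one caller archetype."""

    method: str
    outward: int  # bp of slack away from the event
    inward: int   # bp of slack into the event

    def __post_init__(self):
        if self.outward < 0 or self.inward < 0:
            raise ValueError("slacks must be >= 0")


#: Published per-tool breakpoint resolutions: PE+SR callers 50 bp outwards /
#: 100 bp inwards, read-depth callers 1 kb outwards / 400 bp inwards,
#: split-read callers +/- 10 bp.
DEFAULT_PROFILES = {
    PE_SR: MethodProfile(PE_SR, outward=50, inward=100),
    RD: MethodProfile(RD, outward=1000, inward=400),
    SR: MethodProfile(SR, outward=10, inward=10),
}


@dataclass(frozen=True)
class RawCall:
    """One duplication prediction from one caller.

    ``start``/``end`` are 0-based half-open. ``sample`` is the sample the
    call was made in (or a population tag for population-mode callers).
    ``support_pairs``/``support_mq`` are the supporting read-pair count and
    the minimum mapping quality of that support, where the caller reports
    them (PE_SR callers do; others may leave them None).
    """

    chrom: str
    start: int
    end: int
    method: str
    sample: str
    support_pairs: Optional[int] = None
    support_mq: Optional[int] = None
    id: Optional[str] = None

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.start}-{self.end}")

    @property
    def size(self) -> int:
        return self.end - self.start

    def with_id(self, call_id: str) -> "RawCall":
        return replace(self, id=call_id)


@dataclass(frozen=True)
class CICall:
    """A raw call with closed breakpoint confidence intervals attached."""

    call: RawCall
    start_ci: Tuple[int, int]
    end_ci: Tuple[int, int]

    def __post_init__(self):
        if not (self.start_ci[0] <= self.call.start <= self.start_ci[1]):
            raise ValueError("start CI does not contain start")
        if not (self.end_ci[0] <= self.call.end <= self.end_ci[1]):
            raise ValueError("end CI does not contain end")

    # convenience pass-throughs
    @property
    def chrom(self) -> str:
        return self.call.chrom

    @property
    def start(self) -> int:
        return self.call.start

    @property
    def end(self) -> int:
        return self.call.end

    @property
    def method(self) -> str:
        return self.call.method

    @property
    def sample(self) -> str:
        return self.call.sample


@dataclass(frozen=True)
class DupLocus:
    """A merged, non-redundant duplication locus.

    ``members`` records the identifiers of the calls merged into this locus;
    ``samples`` the samples those calls came from; ``species`` the species
    tags present (populated by the cross-species merge). ``start_ci`` /
    ``end_ci`` are consensus breakpoint confidence intervals (the union of
    the member CIs), used by the long-read validation stage.
    """

    chrom: str
    start: int
    end: int
    methods: FrozenSet[str] = frozenset()
    members: Tuple[str, ...] = ()
    samples: FrozenSet[str] = frozenset()
    species: FrozenSet[str] = frozenset()
    id: Optional[str] = None
    start_ci: Optional[Tuple[int, int]] = None
    end_ci: Optional[Tuple[int, int]] = None

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"locus end {self.end} <= start {self.start}")

    @property
    def size(self) -> int:
        """Locus size in bp (half-open: ``end - start``)."""
        return self.end - self.start

    @property
    def interval(self) -> Tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def with_id(self, locus_id: str) -> "DupLocus":
        return replace(self, id=locus_id)
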