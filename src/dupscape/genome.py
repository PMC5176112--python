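"""Reference coordinate space: ordered chromosomes with lengths."""

from __future__ import annotations

from typing import Iterable, Iterator, Mapping, Tuple


class GenomeIndex:
    """Ordered chromosome names with lengths (bp).

    The coordinate space every interval in the package lives in. Coordinates
    are 0-based half-open throughout (BED convention); conversion to/from
    1-based formats (GFF3, VCF) happens only at I/O boundaries.

    Parameters
    ----------
    chromosomes
        Mapping or iterable of ``(name, length)`` pairs; order is preserved
        and meaningful (it is the genome order used for output sorting).
    """

    def __init__(self, chromosomes: Mapping[str, int] | Iterable[Tuple[str, int]]):
        items = list(chromosomes.items()) if isinstance(chromosomes, Mapping) else list(chromosomes)
        names = [str(n) for n, _ in items]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        lengths = {}
        for name, length in items:
            length = int(length)
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
            lengths[str(name)] = length
        self._names = names
        self._lengths = lengths

    @property
    def names(self) -> list[str]:
        return list(self._names)

    def length(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    @property
    def total_length(self) -> int:
        return sum(self._lengths.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def __len__(self) -> int:
        return len(self._names)

    def __iter__(self) -> Iterator[Tuple[str, int]]:
        for name in self._names:
            yield name, self._lengths[name]

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenomeIndex):
            return NotImplemented
        return self._names == other._names and self._lengths == other._lengths

    def __repr__(self) -> str:
        return f"GenomeIndex({len(self)} chromosomes, {self.total_length} bp)"

    def validate_interval(self, chrom: str, start: int, end: int) -> None:
        """Raise ValueError unless ``0 <= start < end <= length(chrom)``."""
        clen = self.length(chrom)
        if not (0 <= start < end <= clen):
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside chromosome bounds [0, {clen}]"
            )

    @classmethod
    def from_tsv(cls, path) -> "GenomeIndex":
        """Read a two-column (name, length) TSV; .fai files work as-is
        (extra columns are ignored)."""
        pairs = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                pairs.append((fields[0], int(fields[1])))
        return cls(pairs)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for name, length in self:
                fh.write(f"{name}\t{length}\n")
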