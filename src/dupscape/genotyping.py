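"""Dominant presence/absence genotyping of duplication loci.

Every duplication is treated as a dominant binary marker: a sample scores 1
when it carries more copies of the locus than the reference genome and 0 when
it has the same copy number, with no attempt to call heterozygotes. Presence
is decided by a transparent evidence threshold (supporting read pairs at the
locus), and two quality filters are applied to the genotyped set: loci whose
median read support exceeds 500 (high-copy repeats) and loci genotyped in no
sample are removed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .calls import DupLocus


@dataclass(frozen=True)
class SampleMeta:
    """One sequenced individual: species tag, sampling location and its
    coordinates (decimal degrees; used as covariates downstream)."""

    id: str
    species: str
    location: str
    lat: float = float("nan")
    lon: float = float("nan")


def genotype_presence(supporting_pairs: Optional[int], min_pairs: int = 3) -> float:
    """Score one locus in one sample: 1 if supporting read pairs >=
    ``min_pairs``, 0 if evidence is present but below threshold, NaN
    (missing) when there is no evidence record."""
    if supporting_pairs is None:
        return float("nan")
    if supporting_pairs < 0:
        raise ValueError(f"negative support count {supporting_pairs}")
    return 1.0 if supporting_pairs >= min_pairs else 0.0


def locus_size(locus: Union[DupLocus, Sequence[int]]) -> int:
    """Size of a duplication locus in bp (half-open: ``end - start``)."""
    if isinstance(locus, DupLocus):
        return locus.size
    start, end = int(locus[0]), int(locus[1])
    if end <= start:
        raise ValueError(f"locus end {end} <= start {start}")
    return end - start


class GenotypeMatrix:
    """Loci x samples dominant genotype matrix (0 / 1 / NaN = missing).

    Parameters
    ----------
    data
        DataFrame indexed by locus id, one column per sample id, values in
        {0, 1, NaN}.
    samples
        Sample metadata, in column order of ``data``.
    median_support
        Per-locus median supporting read count over non-missing samples.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        samples: Sequence[SampleMeta],
        median_support: Optional[pd.Series] = None,
    ):
        sample_ids = [s.id for s in samples]
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample identifiers")
        if list(data.columns) != sample_ids:
            raise ValueError("data columns do not match sample metadata order")
        self.data = data.astype(float)
        self.samples = list(samples)
        if median_support is None:
            median_support = pd.Series(np.nan, index=data.index)
        self.median_support = median_support.reindex(data.index)

    # -- construction -------------------------------------------------------

    @classmethod
    def from_evidence(
        cls,
        evidence: pd.DataFrame,
        loci: Iterable[str],
        samples: Sequence[SampleMeta],
        min_pairs: int = 3,
    ) -> "GenotypeMatrix":
        """Build the matrix from a long evidence table with columns
        ``locus``, ``sample``, ``supporting_pairs``. Locus/sample pairs with
        no record are scored missing."""
        if (evidence["supporting_pairs"] < 0).any():
            raise ValueError("negative support counts in evidence table")
        loci = list(loci)
        sample_ids = [s.id for s in samples]
        support = evidence.pivot_table(
            index="locus", columns="sample", values="supporting_pairs", aggfunc="max"
        ).reindex(index=loci, columns=sample_ids)
        geno = (support >= min_pairs).astype(float)
        geno[support.isna()] = np.nan
        med = support.median(axis=1, skipna=True)
        return cls(geno, samples, median_support=med)

    # -- filters -------------------------------------------------------------

    def filter_genotyped_set(self, max_median_support: float = 500) -> "GenotypeMatrix":
        """Drop loci whose median read support exceeds ``max_median_support``
        (strictly) and loci with no non-missing genotype in any sample."""
        too_deep = self.median_support > max_median_support
        all_missing = self.data.isna().all(axis=1)
        keep = ~(too_deep.fillna(False) | all_missing)
        return GenotypeMatrix(
            self.data.loc[keep], self.samples, self.median_support.loc[keep]
        )

    # -- summaries -----------------------------------------------------------

    def group_ids(self, species: Optional[str] = None, location: Optional[str] = None) -> List[str]:
        out = []
        for s in self.samples:
            if species is not None and s.species != species:
                continue
            if location is not None and s.location != location:
                continue
            out.append(s.id)
        return out

    def presence_frequency(self, locus: str, group: Sequence[str]) -> float:
        """Fraction of non-missing samples in ``group`` carrying the locus."""
        if not len(group):
            raise ValueError("empty sample group")
        row = self.data.loc[locus, list(group)]
        n = row.notna().sum()
        if n == 0:
            raise ValueError(f"locus {locus!r} has no genotyped sample in group")
        return float((row == 1).sum() / n)

    def singleton_fraction(self, group: Sequence[str]) -> float:
        """Fraction of loci present in exactly one sample of ``group``."""
        if not len(group):
            raise ValueError("empty sample group")
        if self.data.shape[0] == 0:
            raise ValueError("empty locus set")
        counts = (self.data[list(group)] == 1).sum(axis=1)
        return float((counts == 1).mean())

    @property
    def loci(self) -> List[str]:
        return list(self.data.index)

    @property
    def shape(self):
        return self.data.shape

    # -- I/O -----------------------------------------------------------------

    def to_tsv(self, path, missing_as_zero: bool = False) -> None:
        df = self.data.fillna(0.0) if missing_as_zero else self.data
        out = df.copy()
        out.insert(0, "median_support", self.median_support)
        out.to_csv(path, sep="\t", index_label="locus", na_rep="NA")

    @classmethod
    def from_tsv(cls, path, samples: Sequence[SampleMeta]) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col="locus", na_values=["NA"])
        med = df.pop("median_support") if "median_support" in df.columns else None
        return cls(df[[s.id for s in samples]], samples, median_support=med)


def read_sample_metadata(path) -> List[SampleMeta]:
    """Read sample metadata TSV (id, species, location, lat, lon)."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        out.append(
            SampleMeta(
                id=str(r["id"]),
                species=str(r["species"]),
                location=str(r["location"]),
                lat=float(r.get("lat", math.nan)),
                lon=float(r.get("lon", math.nan)),
            )
        )
    return out


def write_sample_metadata(samples: Sequence[SampleMeta], path) -> None:
    pd.DataFrame(
        [(s.id, s.species, s.location, s.lat, s.lon) for s in samples],
        columns=["id", "species", "location", "lat", "lon"],
    ).to_csv(path, sep="\t", index=False)
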