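"""Readers and writers for the pipeline's text formats.

Calls travel as 6+-column TSV (chrom, start, end, method, sample, support)
or as VCF ``SVTYPE=DUP`` records (via pysam); merged loci as BED-like TSV;
split reads as LUMPY-dialect BEDPE. Internally everything is 0-based
half-open; VCF conversion (1-based POS, inclusive END) happens here only.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Dict, List, Optional, Sequence

from .calls import DupLocus, RawCall
from .genome import GenomeIndex
from .longread import Segment, SplitReadAlignment

CALL_COLUMNS = ["chrom", "start", "end", "method", "sample",
                "support_pairs", "support_mq", "id"]


# ---------------------------------------------------------------------------
# raw calls: TSV


def write_calls_tsv(calls: Sequence[RawCall], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(CALL_COLUMNS)
        for c in sorted(calls, key=lambda c: (c.chrom, c.start, c.end, c.sample)):
            w.writerow(
                [c.chrom, c.start, c.end, c.method, c.sample,
                 "" if c.support_pairs is None else c.support_pairs,
                 "" if c.support_mq is None else c.support_mq,
                 c.id or ""]
            )


def read_calls_tsv(path) -> List[RawCall]:
    out = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(
                RawCall(
                    chrom=row["chrom"], start=int(row["start"]), end=int(row["end"]),
                    method=row["method"], sample=row["sample"],
                    support_pairs=int(row["support_pairs"]) if row.get("support_pairs") else None,
                    support_mq=int(row["support_mq"]) if row.get("support_mq") else None,
                    id=row.get("id") or None,
                )
            )
    return out


# ---------------------------------------------------------------------------
# raw calls: VCF (SVTYPE=DUP)


def write_calls_vcf(calls: Sequence[RawCall], genome: GenomeIndex, path) -> None:
    """Write duplication calls as VCF DUP records (1-based POS, inclusive
    INFO/END; PE = supporting pairs, MAPQ = support mapping quality)."""
    import pysam

    header = pysam.VariantHeader()
    for name, length in genome:
        header.contigs.add(name, length=length)
    header.info.add("END", 1, "Integer", "End position of the variant")
    header.info.add("SVTYPE", 1, "String", "Type of structural variant")
    header.info.add("METHOD", 1, "String", "Caller archetype (PE_SR/SR/RD)")
    header.info.add("SAMPLE", 1, "String", "Sample or population tag")
    header.info.add("PE", 1, "Integer", "Supporting read pairs")
    header.info.add("MAPQ", 1, "Integer", "Minimum mapping quality of support")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for i, c in enumerate(
            sorted(calls, key=lambda c: (c.chrom, c.start, c.end, c.sample)), 1
        ):
            rec = vcf.new_record(
                contig=c.chrom, start=c.start, stop=c.end,
                alleles=("N", "<DUP>"), id=c.id or f"DUPCALL{i:06d}",
            )
            rec.info["SVTYPE"] = "DUP"
            rec.info["METHOD"] = c.method
            rec.info["SAMPLE"] = c.sample
            if c.support_pairs is not None:
                rec.info["PE"] = c.support_pairs
            if c.support_mq is not None:
                rec.info["MAPQ"] = c.support_mq
            vcf.write(rec)


def read_calls_vcf(path, method: Optional[str] = None, sample: Optional[str] = None) -> List[RawCall]:
    """Read VCF DUP records as raw calls. Non-DUP records (deletions,
    inversions, ...) are ignored; method/sample fall back to the given
    defaults when the INFO keys are absent."""
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            svtype = _info_get(rec, "SVTYPE")
            if svtype is None and rec.alts:
                svtype = rec.alts[0].strip("<>")
            if svtype != "DUP":
                continue
            m = _info_get(rec, "METHOD", method)
            s = _info_get(rec, "SAMPLE", sample)
            if m is None or s is None:
                raise ValueError(
                    f"record {rec.id}: METHOD/SAMPLE not in INFO and no default given"
                )
            out.append(
                RawCall(
                    chrom=rec.contig, start=rec.start, end=rec.stop,
                    method=str(m), sample=str(s),
                    support_pairs=_info_get(rec, "PE"),
                    support_mq=_info_get(rec, "MAPQ"),
                    id=rec.id,
                )
            )
    return out


def _info_get(rec, key, default=None):
    """INFO lookup tolerant of keys absent from the VCF header (pysam raises
    rather than returning the default for undeclared keys)."""
    try:
        val = rec.info.get(key, default)
    except (KeyError, ValueError):
        return default
    return val


# ---------------------------------------------------------------------------
# merged loci: BED-like TSV

LOCUS_COLUMNS = ["chrom", "start", "end", "id", "size", "methods", "species",
                 "n_members", "samples"]


def write_loci_tsv(loci: Sequence[DupLocus], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(LOCUS_COLUMNS)
        for l in loci:
            w.writerow(
                [l.chrom, l.start, l.end, l.id or "", l.size,
                 ",".join(sorted(l.methods)), ",".join(sorted(l.species)),
                 len(l.members), ",".join(sorted(l.samples))]
            )


def read_loci_tsv(path) -> List[DupLocus]:
    out = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                DupLocus(
                    chrom=row["chrom"], start=int(row["start"]), end=int(row["end"]),
                    id=row.get("id") or None,
                    methods=frozenset(filter(None, row.get("methods", "").split(","))),
                    species=frozenset(filter(None, row.get("species", "").split(","))),
                    samples=frozenset(filter(None, row.get("samples", "").split(","))),
                    members=(row.get("id") or f"{row['chrom']}:{row['start']}",),
                )
            )
    return out


# ---------------------------------------------------------------------------
# split reads: BEDPE (LUMPY splitReadSamToBedpe dialect)
#
# chrom1 start1 end1 chrom2 start2 end2 readname score strand1 strand2
# Block 1 is the segment that comes earlier in read coordinates; one line per
# adjacent segment pair. Read coordinates are not representable in BEDPE, so
# on re-import they are synthesised from segment lengths in line order.


def write_bedpe(reads: Sequence[SplitReadAlignment], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for r in reads:
            for a, b in zip(r.segments, r.segments[1:]):
                w.writerow(
                    [a.chrom, a.ref_start, a.ref_end,
                     b.chrom, b.ref_start, b.ref_end,
                     r.read_id, 0, a.strand, b.strand]
                )


def read_bedpe(path) -> List[SplitReadAlignment]:
    pairs: Dict[str, List[Segment]] = {}
    order: List[str] = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 10:
                continue
            name = f[6]
            if name not in pairs:
                pairs[name] = []
                order.append(name)
            segs = pairs[name]
            a = (f[0], int(f[1]), int(f[2]), f[8])
            b = (f[3], int(f[4]), int(f[5]), f[9])
            if not segs or segs[-1] != a:
                segs.append(a)
            segs.append(b)
    out = []
    for name in order:
        cursor = 0
        segments = []
        for chrom, s, e, strand in pairs[name]:
            segments.append(
                Segment(chrom=chrom, ref_start=s, ref_end=e,
                        read_start=cursor, read_end=cursor + (e - s), strand=strand)
            )
            cursor += e - s
        out.append(SplitReadAlignment(read_id=name, segments=tuple(segments)))
    return out
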