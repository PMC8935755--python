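"""Readers and writers for the standard formats the pipeline touches.

Pool variants arrive as VCF 4.x with a per-sample ``AD`` (allelic depth)
FORMAT field; gene anchors as GFF3; markers and chromosome lengths as TSV;
haplotype-frequency results leave as TSV (and windows optionally as BED).
All coordinates are 1-based inclusive internally (VCF/GFF convention);
only BED export converts to 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
import pysam

log = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "VariantSite",
    "GeneAnnotation",
    "MarkerRecord",
    "ChromosomeTable",
    "read_vcf_sites",
    "write_vcf_sites",
    "read_gff_genes",
    "read_marker_table",
    "write_marker_table",
    "read_chrom_table",
    "write_chrom_table",
    "write_haf_table",
    "read_haf_table",
    "write_windows_tsv",
    "read_windows_tsv",
    "write_windows_bed",
    "read_parental_tsv",
    "write_parental_tsv",
    "parental_genotypes_from_vcf",
]


class FormatError(ValueError):
    """An input file violates the expected format contract."""


@dataclass(frozen=True, slots=True)
class VariantSite:
    """One biallelic SNP record with the pool sample's allelic depths."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    qual: float
    ref_reads: int
    alt_reads: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_reads < 0 or self.alt_reads < 0:
            raise ValueError("read counts must be non-negative")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt allele must differ")

    @property
    def total_reads(self) -> int:
        return self.ref_reads + self.alt_reads


@dataclass(frozen=True, slots=True)
class GeneAnnotation:
    """A gene interval used as a haplotype anchor."""

    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "."
    confidence: str = "high"  # high|low

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


@dataclass(frozen=True, slots=True)
class MarkerRecord:
    """A chip marker with a physical and (optionally) genetic position."""

    marker_id: str
    chrom: str
    pos_bp: int
    pos_cM: float | None = None

    def __post_init__(self) -> None:
        if self.pos_bp < 1:
            raise ValueError(f"marker {self.marker_id}: pos_bp must be >= 1")


class ChromosomeTable:
    """Chromosome names and lengths (FAI-style)."""

    def __init__(self, lengths: dict[str, int]):
        if len(lengths) == 0:
            raise ValueError("chromosome table is empty")
        for name, length in lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name}: non-positive length")
        self._lengths = dict(lengths)

    def __contains__(self, name: str) -> bool:
        return name in self._lengths

    def __len__(self) -> int:
        return len(self._lengths)

    def length(self, name: str) -> int:
        return self._lengths[name]

    @property
    def names(self) -> list[str]:
        return list(self._lengths)

    def items(self):
        return self._lengths.items()


# ---------------------------------------------------------------------------
# VCF

def passes_site_filters(
    qual: float | None,
    total_reads: int,
    min_qual: float,
) -> bool:
    """Shared SNP filter: quality strictly above threshold, >= 1 read."""
    return qual is not None and qual > min_qual and total_reads >= 1


def read_vcf_sites(
    path: str | Path,
    min_qual: float = 30.0,
    whitelist: set[tuple[str, int]] | None = None,
    sample: str | None = None,
) -> list[VariantSite]:
    """Read biallelic SNPs with pool allelic depths from a VCF.

    Keeps records with QUAL strictly greater than ``min_qual`` (the tool's
    convention is "exceed", not "at least"), at least one supporting read in
    the pool sample, and — if a whitelist of (chrom, pos) is given — position
    membership in the whitelist. Indels and multiallelic records are skipped
    with a logged count. Records with a missing per-sample AD value are
    skipped; a VCF whose FORMAT lacks AD entirely is a format error.
    """
    if min_qual < 0:
        raise ValueError("min_qual must be >= 0")
    path = str(path)
    vcf = pysam.VariantFile(path)
    if "AD" not in vcf.header.formats:
        raise FormatError(f"{path}: FORMAT/AD is required for pool depths")
    samples = list(vcf.header.samples)
    if not samples:
        raise FormatError(f"{path}: VCF has no samples")
    if sample is None:
        sample = samples[0]
    elif sample not in samples:
        raise FormatError(f"{path}: sample {sample!r} not in VCF")

    sites: list[VariantSite] = []
    n_indel = n_multi = n_noad = n_lowq = n_noreads = n_whitelist = 0
    for rec in vcf:
        alts = rec.alts
        if alts is None or len(alts) == 0:
            continue
        if len(alts) > 1:
            n_multi += 1
            continue
        alt = alts[0]
        if alt is None or len(rec.ref) != 1 or len(alt) != 1:
            n_indel += 1
            continue
        ad = rec.samples[sample].get("AD")
        if ad is None or len(ad) < 2 or ad[0] is None or ad[1] is None:
            n_noad += 1
            continue
        ref_reads, alt_reads = int(ad[0]), int(ad[1])
        qual = rec.qual
        if qual is None or qual <= min_qual:
            n_lowq += 1
            continue
        if ref_reads + alt_reads < 1:
            n_noreads += 1
            continue
        if whitelist is not None and (rec.chrom, rec.pos) not in whitelist:
            n_whitelist += 1
            continue
        sites.append(
            VariantSite(rec.chrom, rec.pos, rec.ref, alt, float(qual),
                        ref_reads, alt_reads)
        )
    vcf.close()

    key = [(s.chrom, s.pos) for s in sites]
    if key != sorted(key):
        log.warning("%s: records not sorted by (chrom, pos); re-sorting", path)
        sites.sort(key=lambda s: (s.chrom, s.pos))
    log.info(
        "%s: kept %d sites (skipped: %d multiallelic, %d indel, %d missing AD,"
        " %d low qual, %d zero depth, %d off-whitelist)",
        path, len(sites), n_multi, n_indel, n_noad, n_lowq, n_noreads,
        n_whitelist,
    )
    return sites


def write_vcf_sites(
    sites: Sequence[VariantSite],
    chrom_table: ChromosomeTable,
    path: str | Path,
    sample: str = "POOL",
) -> None:
    """Write pool sites as an uncompressed VCF with FORMAT/AD."""
    header = pysam.VariantHeader()
    header.add_meta("source", "poolhaf")
    for name, length in chrom_table.items():
        header.contigs.add(name, length=length)
    header.formats.add("AD", "R", "Integer",
                       "Allelic depths for the ref and alt alleles")
    header.add_sample(sample)
    out = pysam.VariantFile(str(path), "w", header=header)
    for s in sites:
        rec = out.new_record(
            contig=s.chrom, start=s.pos - 1, stop=s.pos,
            alleles=(s.ref_allele, s.alt_allele), qual=s.qual,
        )
        rec.samples[sample]["AD"] = (s.ref_reads, s.alt_reads)
        out.write(rec)
    out.close()


# ---------------------------------------------------------------------------
# GFF3 genes

_CONF_KEYS = ("primary_confidence_class", "confidence", "conf_class")
_LOW_VALUES = {"lc", "low", "low_confidence", "lowconf"}


def read_gff_genes(path: str | Path, confidence_filter: str = "high") -> list[GeneAnnotation]:
    """Read gene features from GFF3, sorted by (chrom, start).

    ``confidence_filter="high"`` drops low-confidence genes; ``"all"`` keeps
    everything. Genes without a recognisable confidence attribute are treated
    as high confidence. Duplicate gene IDs raise an error.
    """
    if confidence_filter not in ("high", "all"):
        raise ValueError("confidence_filter must be 'high' or 'all'")
    db = gffutils.create_db(
        str(path), dbfn=":memory:", keep_order=True,
        merge_strategy="error",  # duplicate gene_ids must not silently merge
    )
    genes: list[GeneAnnotation] = []
    for feat in db.features_of_type("gene"):
        conf = "high"
        for key in _CONF_KEYS:
            if key in feat.attributes:
                value = feat.attributes[key][0].lower()
                conf = "low" if value in _LOW_VALUES else "high"
                break
        if confidence_filter == "high" and conf == "low":
            continue
        genes.append(
            GeneAnnotation(feat.id, feat.seqid, feat.start, feat.end,
                           feat.strand or ".", conf)
        )
    genes.sort(key=lambda g: (g.chrom, g.start, g.end, g.gene_id))
    return genes


# ---------------------------------------------------------------------------
# Marker and chromosome tables

def read_marker_table(path: str | Path) -> list[MarkerRecord]:
    """TSV with columns marker_id, chrom, pos_bp and optional pos_cM."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     float_precision="round_trip")
    required = {"marker_id", "chrom", "pos_bp"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: marker table needs columns {sorted(required)}")
    if df["marker_id"].duplicated().any():
        dup = df.loc[df["marker_id"].duplicated(), "marker_id"].iloc[0]
        raise FormatError(f"{path}: duplicate marker_id {dup!r}")
    has_cm = "pos_cM" in df.columns
    out = []
    for row in df.itertuples(index=False):
        cm = getattr(row, "pos_cM", None) if has_cm else None
        if cm is not None and pd.isna(cm):
            cm = None
        out.append(MarkerRecord(str(row.marker_id), str(row.chrom),
                                int(row.pos_bp), None if cm is None else float(cm)))
    return out


def write_marker_table(markers: Sequence[MarkerRecord], path: str | Path,
                       header_comment: str | None = None) -> None:
    df = pd.DataFrame(
        {
            "marker_id": [m.marker_id for m in markers],
            "chrom": [m.chrom for m in markers],
            "pos_bp": [m.pos_bp for m in markers],
            "pos_cM": [m.pos_cM for m in markers],
        }
    )
    _write_tsv(df, path, header_comment)


def read_chrom_table(path: str | Path) -> ChromosomeTable:
    """FAI-style TSV: first two columns are chromosome name and length."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need at least two columns (name, length)")
    names = df.iloc[:, 0].astype(str)
    if names.duplicated().any():
        raise FormatError(f"{path}: duplicate chromosome names")
    return ChromosomeTable(dict(zip(names, df.iloc[:, 1].astype(int))))


def write_chrom_table(chrom_table: ChromosomeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in chrom_table.items():
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# HAF tables

HAF_COLUMNS = ["chrom", "start", "end", "anchor_id", "anchor_type",
               "n_snps", "total_reads", "haf"]


def write_haf_table(records: Sequence, path: str | Path,
                    header_comment: str | None = None) -> None:
    """Write haplotype-frequency records as TSV (lossless round trip).

    Frequencies are serialised with the shortest representation that
    round-trips bit-exactly through the matching reader.
    """
    df = pd.DataFrame(
        {
            "chrom": [r.chrom for r in records],
            "start": [r.start for r in records],
            "end": [r.end for r in records],
            "anchor_id": [r.anchor_id for r in records],
            "anchor_type": [r.anchor_type for r in records],
            "n_snps": [r.n_snps for r in records],
            "total_reads": [r.total_reads for r in records],
            "haf": [repr(float(r.haf)) for r in records],
        }
    )
    _write_tsv(df, path, header_comment)


def read_haf_table(path: str | Path):
    """Read a HAF TSV back into HaplotypeFrequencyRecords (no member SNPs)."""
    from .frequency import HaplotypeFrequencyRecord  # local: avoid cycle

    df = pd.read_csv(path, sep="\t", comment="#",
                     float_precision="round_trip")
    missing = set(HAF_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: HAF table missing columns {sorted(missing)}")
    return [
        HaplotypeFrequencyRecord(
            anchor_id=str(r.anchor_id), chrom=str(r.chrom), start=int(r.start),
            end=int(r.end), anchor_type=str(r.anchor_type), haf=float(r.haf),
            total_reads=int(r.total_reads), n_snps=int(r.n_snps),
            member_freqs=(),
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Window tables

WINDOW_COLUMNS = ["anchor_id", "chrom", "start", "end", "core_start",
                  "core_end", "anchor_type"]


def write_windows_tsv(windows: Sequence, path: str | Path,
                      header_comment: str | None = None) -> None:
    df = pd.DataFrame([
        {
            "anchor_id": w.anchor_id, "chrom": w.chrom, "start": w.start,
            "end": w.end, "core_start": w.core_start, "core_end": w.core_end,
            "anchor_type": w.anchor_type,
        }
        for w in windows
    ], columns=WINDOW_COLUMNS)
    _write_tsv(df, path, header_comment)


def read_windows_tsv(path: str | Path):
    from .windows import HaplotypeWindow  # local: avoid cycle

    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(WINDOW_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: window table missing columns {sorted(missing)}")
    return [
        HaplotypeWindow(
            anchor_id=str(r.anchor_id), chrom=str(r.chrom), start=int(r.start),
            end=int(r.end), core_start=int(r.core_start),
            core_end=int(r.core_end), anchor_type=str(r.anchor_type),
        )
        for r in df.itertuples(index=False)
    ]


def write_windows_bed(windows: Sequence, path: str | Path,
                      header_comment: str | None = None) -> None:
    """BED export (0-based half-open); name=anchor_id, score=span in bp."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"#{header_comment}\n")
        for w in windows:
            span = w.end - w.start + 1
            fh.write(f"{w.chrom}\t{w.start - 1}\t{w.end}\t{w.anchor_id}\t{span}\n")


# ---------------------------------------------------------------------------
# Parental genotypes

def read_parental_tsv(path: str | Path):
    """TSV with columns chrom, pos, donor_allele, recurrent_allele."""
    from .frequency import ParentalGenotypes

    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"chrom", "pos", "donor_allele", "recurrent_allele"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: parental table needs columns {sorted(required)}")
    alleles = {
        (str(r.chrom), int(r.pos)): (str(r.donor_allele), str(r.recurrent_allele))
        for r in df.itertuples(index=False)
    }
    return ParentalGenotypes(alleles)


def write_parental_tsv(parents, path: str | Path,
                       header_comment: str | None = None) -> None:
    rows = [
        {"chrom": chrom, "pos": pos, "donor_allele": donor,
         "recurrent_allele": recurrent}
        for (chrom, pos), (donor, recurrent) in sorted(parents.items())
    ]
    df = pd.DataFrame(rows, columns=["chrom", "pos", "donor_allele",
                                     "recurrent_allele"])
    _write_tsv(df, path, header_comment)


def parental_genotypes_from_vcf(path: str | Path, donor_sample: str,
                                recurrent_sample: str):
    """Derive donor/recurrent alleles from a two-parent VCF.

    Only sites where both parents are homozygous for different alleles are
    retained — the polarisation contract of the frequency module.
    """
    from .frequency import ParentalGenotypes

    vcf = pysam.VariantFile(str(path))
    for name in (donor_sample, recurrent_sample):
        if name not in list(vcf.header.samples):
            raise FormatError(f"{path}: sample {name!r} not in VCF")
    alleles: dict[tuple[str, int], tuple[str, str]] = {}
    for rec in vcf:
        if rec.alts is None or len(rec.alts) != 1:
            continue
        if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
            continue
        gt_d = rec.samples[donor_sample].get("GT")
        gt_r = rec.samples[recurrent_sample].get("GT")
        if gt_d is None or gt_r is None or None in gt_d or None in gt_r:
            continue
        if len(set(gt_d)) != 1 or len(set(gt_r)) != 1 or gt_d[0] == gt_r[0]:
            continue
        bases = (rec.ref, rec.alts[0])
        alleles[(rec.chrom, rec.pos)] = (bases[gt_d[0]], bases[gt_r[0]])
    vcf.close()
    return ParentalGenotypes(alleles)


# ---------------------------------------------------------------------------

def _write_tsv(df: pd.DataFrame, path: str | Path,
               header_comment: str | None = None,
               float_format: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"#{header_comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=float_format)
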