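"""Polarised SNP frequencies and their aggregation into haplotype
allele frequencies (HAF).

The pool read counts at each biallelic SNP are polarised to the donor
parent (sites where the two inbred parents carry different homozygous
alleles). Within a haplotype window the member SNP frequencies are combined
into a single depth-weighted estimate

    HAF_p = sum_k(rd_k * freq_pk) / sum_k(rd_k)

which equals total donor reads over total reads; aggregation therefore
conserves read counts exactly in integer arithmetic. The recurrent parent's
HAF is 1 - HAF_p.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import VariantSite
from .windows import HaplotypeWindow

__all__ = [
    "ParentalGenotypes",
    "SnpFrequencyRecord",
    "HaplotypeFrequencyRecord",
    "polarize_snp",
    "polarize_sites",
    "haplotype_allele_frequency",
    "genome_wide_frequency",
]

# rejection reasons used by polarize_sites
NOT_PARENTAL = "not_parental"
ALLELE_MISMATCH = "allele_mismatch"


class ParentalGenotypes(Mapping):
    """Donor/recurrent allele per site, for sites where both parents are
    homozygous for different alleles."""

    def __init__(self, alleles: dict[tuple[str, int], tuple[str, str]]):
        for key, (donor, recurrent) in alleles.items():
            if donor == recurrent:
                raise ValueError(f"{key}: donor and recurrent allele identical")
        self._alleles = dict(alleles)

    def __getitem__(self, key):
        return self._alleles[key]

    def __iter__(self):
        return iter(self._alleles)

    def __len__(self):
        return len(self._alleles)


@dataclass(frozen=True, slots=True)
class SnpFrequencyRecord:
    """Donor allele frequency and read depth at one polarised SNP."""

    chrom: str
    pos: int
    freq: float  # donor allele frequency in the pool, [0, 1]
    depth: int  # total reads at the SNP
    donor_reads: int

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0 <= self.donor_reads <= self.depth:
            raise ValueError("donor_reads must lie in [0, depth]")
        if not 0.0 <= self.freq <= 1.0:
            raise ValueError("freq must lie in [0, 1]")


@dataclass(frozen=True, slots=True)
class HaplotypeFrequencyRecord:
    """Depth-weighted donor HAF of one window with member provenance."""

    anchor_id: str
    chrom: str
    start: int
    end: int
    anchor_type: str
    haf: float
    total_reads: int
    n_snps: int
    member_freqs: tuple[SnpFrequencyRecord, ...] = ()

    @property
    def donor_reads(self) -> int:
        if self.member_freqs:
            return sum(m.donor_reads for m in self.member_freqs)
        return round(self.haf * self.total_reads)


def polarize_snp(site: VariantSite, parents: ParentalGenotypes
                 ) -> SnpFrequencyRecord | None:
    """Polarise one pool site to the donor parent.

    Returns None when the site is not a parental-difference site or when the
    donor allele matches neither REF nor ALT (use :func:`polarize_sites` for
    per-reason rejection counts).
    """
    rec, _ = _polarize(site, parents)
    return rec


def polarize_sites(sites: Iterable[VariantSite], parents: ParentalGenotypes
                   ) -> tuple[list[SnpFrequencyRecord], dict[str, int]]:
    """Polarise a site stream; returns (records, rejection counts by reason)."""
    records: list[SnpFrequencyRecord] = []
    rejected = {NOT_PARENTAL: 0, ALLELE_MISMATCH: 0}
    for site in sites:
        rec, reason = _polarize(site, parents)
        if rec is not None:
            records.append(rec)
        else:
            rejected[reason] += 1
    return records, rejected


def _polarize(site: VariantSite, parents: ParentalGenotypes):
    key = (site.chrom, site.pos)
    if key not in parents:
        return None, NOT_PARENTAL
    donor, recurrent = parents[key]
    if donor == site.alt_allele and recurrent == site.ref_allele:
        donor_reads = site.alt_reads
    elif donor == site.ref_allele and recurrent == site.alt_allele:
        donor_reads = site.ref_reads
    else:
        return None, ALLELE_MISMATCH
    depth = site.total_reads
    if depth < 1:
        return None, NOT_PARENTAL  # filtered upstream; defensive
    return SnpFrequencyRecord(site.chrom, site.pos, donor_reads / depth,
                              depth, donor_reads), None


def haplotype_allele_frequency(
    members: Sequence[SnpFrequencyRecord],
    window: HaplotypeWindow,
) -> HaplotypeFrequencyRecord:
    """Aggregate member SNPs of one window into its donor HAF.

    The estimate is computed from integer read counts (total donor reads /
    total reads), so conservation holds exactly. Raises on an empty member
    list — windows without SNPs are reported with n_snps=0 by the callers'
    diagnostics instead of producing a record.
    """
    if len(members) == 0:
        raise ValueError(f"window {window.anchor_id}: no member SNPs")
    for m in members:
        if m.chrom != window.chrom or not window.start <= m.pos <= window.end:
            raise ValueError(
                f"SNP {m.chrom}:{m.pos} lies outside window {window.anchor_id}"
            )
    donor = sum(m.donor_reads for m in members)
    total = sum(m.depth for m in members)
    return HaplotypeFrequencyRecord(
        anchor_id=window.anchor_id, chrom=window.chrom, start=window.start,
        end=window.end, anchor_type=window.anchor_type, haf=donor / total,
        total_reads=total, n_snps=len(members), member_freqs=tuple(members),
    )


def genome_wide_frequency(records: Sequence) -> float:
    """Read-weighted mean donor frequency over SNP or HAF records.

    Weighting by reads (total donor reads over total reads) keeps the
    estimate consistent with the HAF estimator and robust to depth
    heterogeneity across loci.
    """
    if len(records) == 0:
        raise ValueError("no records")
    donor = 0
    total = 0
    for r in records:
        if isinstance(r, SnpFrequencyRecord):
            donor += r.donor_reads
            total += r.depth
        else:
            donor += r.donor_reads
            total += r.total_reads
    if total == 0:
        raise ValueError("zero total reads")
    return donor / total
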