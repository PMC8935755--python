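"""Synthetic backcross populations, pooled reads, and the in-silico
coverage-vs-accuracy recovery experiment.

The generator emulates a BC2F3 selfing population of a biparental barley
cross: two fully homozygous, opposite founders; meioses under Haldane's
no-interference model (crossover count Poisson with mean equal to the map
length in Morgans, breakpoints uniform in cM); two backcrosses to the
recurrent parent followed by two selfing generations. A pool of 300
genotypes is sampled, per-SNP read counts are drawn at Poisson mean depth
10 (binomial donor reads at the pooled truth frequency), pseudo-SNPs placed
on a fixed 1500 bp grid inside marker linkage windows (MLWs) inherit their
anchor marker's truth, and the depth-weighted HAF is compared with the
population's true donor frequencies.

Read simulation operates at allele-count (AD) level, not at base level:
the pipeline consumes VCF-style counts, so alignment is bypassed while the
binomial sampling structure at a given depth is preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .frequency import (
    ParentalGenotypes,
    haplotype_allele_frequency,
    polarize_sites,
)
from .io_formats import ChromosomeTable, MarkerRecord, VariantSite
from .stats import pearson_r, rmse
from .windows import (
    HaplotypeWindow,
    anchors_from_markers,
    assign_snps,
    extend_anchors,
    filter_windows,
)

log = logging.getLogger(__name__)

__all__ = [
    "SimChromosome",
    "SimGenome",
    "CrossingScheme",
    "SimulatedPopulation",
    "PoolReadModel",
    "default_genome",
    "field_population_scheme",
    "simulate_population",
    "sample_pool",
    "simulate_pool_reads",
    "build_mlw",
    "recovery_experiment",
]


@dataclass(frozen=True, slots=True)
class SimChromosome:
    name: str
    length_bp: int
    map_length_cM: float


@dataclass(frozen=True)
class SimGenome:
    """A marker-grid genome: physical and genetic marker positions.

    ``markers`` is a DataFrame with columns marker_id, chrom, pos_bp,
    pos_cM, sorted by (chrom, pos_bp); cM positions must be monotone in bp
    within each chromosome.
    """

    chromosomes: tuple[SimChromosome, ...]
    markers: pd.DataFrame
    pseudo_snp_spacing: int = 1500

    def __post_init__(self) -> None:
        if self.pseudo_snp_spacing < 1:
            raise ValueError("pseudo_snp_spacing must be >= 1")
        if len(self.markers) == 0:
            raise ValueError("marker grid is empty")
        for chrom in self.markers["chrom"].unique():
            sub = self.markers[self.markers["chrom"] == chrom]
            if not (np.all(np.diff(sub["pos_bp"]) > 0)
                    and np.all(np.diff(sub["pos_cM"]) >= 0)):
                raise ValueError(f"{chrom}: marker positions must be monotone")

    @property
    def chrom_table(self) -> ChromosomeTable:
        return ChromosomeTable({c.name: c.length_bp for c in self.chromosomes})

    def marker_records(self) -> list[MarkerRecord]:
        return [
            MarkerRecord(str(r.marker_id), str(r.chrom), int(r.pos_bp),
                         float(r.pos_cM))
            for r in self.markers.itertuples(index=False)
        ]


@dataclass(frozen=True, slots=True)
class CrossingScheme:
    """Backcross-selfing pedigree producing the population.

    With ``bc_family_sizes=None`` every individual descends through its own
    independent chain of backcross plants — the clean setting for checking
    Mendelian expectations. With family sizes (one per backcross
    generation, e.g. ``(6, 24)``) the population descends from that limited
    set of plants, which is what a real breeding program looks like and
    what drives between-locus drift of the true allele frequency.
    """

    n_backcrosses: int = 2
    n_selfings: int = 2
    donor_label: str = "donor"
    recurrent_label: str = "recurrent"
    bc_family_sizes: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_backcrosses < 0 or self.n_selfings < 0:
            raise ValueError("generation counts must be >= 0")
        if self.bc_family_sizes is not None:
            if len(self.bc_family_sizes) != self.n_backcrosses:
                raise ValueError(
                    "bc_family_sizes needs one entry per backcross generation"
                )
            if any(s < 1 for s in self.bc_family_sizes):
                raise ValueError("family sizes must be >= 1")


def field_population_scheme() -> CrossingScheme:
    """BC2F3 pedigree of a field population descending from 6 BC1 and 24
    BC2 plants; the limited founder set gives the between-locus drift in
    true donor frequency that a bulk-propagated backcross population shows.
    """
    return CrossingScheme(n_backcrosses=2, n_selfings=2,
                          bc_family_sizes=(6, 24))


@dataclass(frozen=True, slots=True)
class PoolReadModel:
    """Sequencing model for pooled read counts at each SNP.

    Depth per SNP is Poisson(``mean_depth``) unless ``fixed_depth`` is set.
    ``read_length`` and ``error_rate`` are carried for provenance; base
    miscalls are not simulated (error_rate default 0). The synthetic
    variant quality is the deterministic, monotone function
    qual = 20 + 10*min(depth, 30), so depth-dependent quality filters are
    exercisable.
    """

    mean_depth: float = 10.0
    fixed_depth: int | None = None
    read_length: int = 100
    error_rate: float = 0.0
    ref_base: str = "A"
    alt_base: str = "T"

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")


def synthetic_qual(depth: np.ndarray) -> np.ndarray:
    return 20.0 + 10.0 * np.minimum(depth, 30)


class SimulatedPopulation:
    """Per-individual donor haplotypes at every marker locus.

    Haplotypes are stored per chromosome as two (n_individuals, n_markers)
    uint8 arrays of donor-origin indicators, aligned with the genome's
    marker table order.
    """

    def __init__(self, genome: SimGenome,
                 haplotypes: dict[str, tuple[np.ndarray, np.ndarray]]):
        self.genome = genome
        self.haplotypes = haplotypes
        first = next(iter(haplotypes.values()))
        self.n_individuals = first[0].shape[0]

    def dosages(self, chrom: str) -> np.ndarray:
        a, b = self.haplotypes[chrom]
        return a.astype(np.uint8) + b.astype(np.uint8)

    def dosage_matrix(self) -> np.ndarray:
        """(n_individuals, n_loci) donor dosages in marker-table order."""
        chroms = [c.name for c in self.genome.chromosomes]
        return np.concatenate([self.dosages(c) for c in chroms
                               if c in self.haplotypes], axis=1)

    def donor_frequencies(self) -> np.ndarray:
        """True donor allele frequency per marker locus."""
        return self.dosage_matrix().mean(axis=0) / 2.0

    def heterozygote_fractions(self) -> np.ndarray:
        """Per-individual fraction of heterozygous marker loci."""
        chroms = [c.name for c in self.genome.chromosomes]
        het = np.concatenate(
            [self.haplotypes[c][0] != self.haplotypes[c][1] for c in chroms
             if c in self.haplotypes], axis=1)
        return het.mean(axis=1)

    def subset(self, indices: np.ndarray) -> "SimulatedPopulation":
        haps = {c: (a[indices], b[indices])
                for c, (a, b) in self.haplotypes.items()}
        return SimulatedPopulation(self.genome, haps)


# ---------------------------------------------------------------------------
# Genome construction

def default_genome(
    rng: np.random.Generator | int | None = None,
    n_chromosomes: int = 7,
    chrom_length_bp: int = 50_000_000,
    map_length_cM: float = 150.0,
    markers_per_chrom: int = 700,
    position_jitter: float = 0.4,
    pseudo_snp_spacing: int = 1500,
) -> SimGenome:
    """Synthetic marker-grid genome mirroring a barley-like karyotype at
    reduced physical scale: 7 chromosomes, 150 cM each, ~4,900 markers.

    Markers sit on a quasi-regular grid with uniform jitter of up to
    ``position_jitter`` times the spacing, which yields marker linkage
    windows with a median of ~43 pseudo-SNPs at the default 1500 bp grid —
    the saturation level the method is designed around. The genetic map is
    linear in physical position.
    """
    rng = _as_rng(rng, fallback=20220321)
    if not 0 <= position_jitter < 0.5:
        raise ValueError("position_jitter must lie in [0, 0.5)")
    chroms = []
    rows = []
    for i in range(n_chromosomes):
        name = f"chr{i + 1}"
        chroms.append(SimChromosome(name, chrom_length_bp, map_length_cM))
        spacing = chrom_length_bp / (markers_per_chrom + 1)
        base = (np.arange(1, markers_per_chrom + 1)) * spacing
        jitter = rng.uniform(-position_jitter, position_jitter,
                             markers_per_chrom) * spacing
        pos = np.clip(np.round(base + jitter).astype(np.int64), 1,
                      chrom_length_bp)
        pos = np.sort(pos)
        pos = _make_strictly_increasing(pos, chrom_length_bp)
        for j, p in enumerate(pos):
            rows.append((f"{name}_m{j + 1:04d}", name, int(p),
                         p * map_length_cM / chrom_length_bp))
    markers = pd.DataFrame(rows, columns=["marker_id", "chrom", "pos_bp",
                                          "pos_cM"])
    return SimGenome(tuple(chroms), markers,
                     pseudo_snp_spacing=pseudo_snp_spacing)


def _make_strictly_increasing(pos: np.ndarray, limit: int) -> np.ndarray:
    for i in range(1, len(pos)):
        if pos[i] <= pos[i - 1]:
            pos[i] = pos[i - 1] + 1
    return np.minimum(pos, limit)


# ---------------------------------------------------------------------------
# Meiosis and crossing

def _as_rng(rng, fallback: int | None = None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    if rng is None:
        rng = fallback
    return np.random.default_rng(rng)


def _meiose_chrom(hap_a: np.ndarray, hap_b: np.ndarray, marker_cM: np.ndarray,
                  map_length_cM: float, rng: np.random.Generator) -> np.ndarray:
    """One gamete per row under Haldane's no-interference model.

    Crossover counts are Poisson(map length in Morgans), breakpoints
    uniform in cM; a marker takes the haplotype selected by the parity of
    crossovers upstream of it plus a fair initial coin.
    """
    n, m = hap_a.shape
    k = rng.poisson(map_length_cM / 100.0, n)
    start = rng.integers(0, 2, n).astype(np.int32)
    total = int(k.sum())
    if total == 0:
        choose = np.broadcast_to(start[:, None] & 1, (n, m))
    else:
        positions = rng.uniform(0.0, map_length_cM, total)
        owner = np.repeat(np.arange(n), k)
        # bin b: the crossover precedes all markers with cM >= position
        b = np.searchsorted(marker_cM, positions, side="left")
        counts = np.zeros((n, m + 1), dtype=np.int32)
        np.add.at(counts, (owner, b), 1)
        upstream = np.cumsum(counts[:, :m], axis=1)
        choose = (start[:, None] + upstream) & 1
    return np.where(choose == 0, hap_a, hap_b).astype(np.uint8)


def _meiose(geno: dict[str, tuple[np.ndarray, np.ndarray]], genome: SimGenome,
            rng: np.random.Generator) -> dict[str, np.ndarray]:
    cm = {c: np.asarray(
        genome.markers.loc[genome.markers["chrom"] == c.name, "pos_cM"],
        dtype=float) for c in genome.chromosomes}
    return {
        c.name: _meiose_chrom(geno[c.name][0], geno[c.name][1], cm[c],
                              c.map_length_cM, rng)
        for c in genome.chromosomes
    }


def simulate_population(
    genome: SimGenome,
    scheme: CrossingScheme,
    n_individuals: int,
    rng: np.random.Generator | int | None = None,
) -> SimulatedPopulation:
    """Simulate the population defined by a backcross-selfing scheme.

    Founders are fully homozygous and opposite (donor x recurrent); the F1
    is uniformly heterozygous. Each backcross generation crosses a gamete
    of the previous generation onto the recurrent parent; each selfing
    generation draws two independent gametes from the same parent plant.
    Loci between markers are below map resolution and inherit the flanking
    segment, so tracking marker loci is exact.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = _as_rng(rng, fallback=0)
    m_by_chrom = {
        c.name: int((genome.markers["chrom"] == c.name).sum())
        for c in genome.chromosomes
    }
    if any(m == 0 for m in m_by_chrom.values()):
        raise ValueError("every chromosome needs at least one marker")

    if scheme.bc_family_sizes is not None:
        sizes = list(scheme.bc_family_sizes)
    else:
        sizes = [n_individuals] * scheme.n_backcrosses

    # F1: donor haplotype + recurrent haplotype, a single plant
    geno = {c: (np.ones((1, m), dtype=np.uint8),
                np.zeros((1, m), dtype=np.uint8))
            for c, m in m_by_chrom.items()}

    for size in sizes:
        parent_idx = np.arange(size) % next(iter(geno.values()))[0].shape[0]
        parents = {c: (a[parent_idx], b[parent_idx])
                   for c, (a, b) in geno.items()}
        gametes = _meiose(parents, genome, rng)
        geno = {c: (g, np.zeros_like(g)) for c, g in gametes.items()}

    # expand to the population and self
    n_last = next(iter(geno.values()))[0].shape[0]
    idx = np.arange(n_individuals) % n_last
    geno = {c: (a[idx], b[idx]) for c, (a, b) in geno.items()}
    for _ in range(scheme.n_selfings):
        parents = geno
        a = _meiose(parents, genome, rng)
        b = _meiose(parents, genome, rng)
        geno = {c: (a[c], b[c]) for c in geno}

    return SimulatedPopulation(genome, geno)


def sample_pool(
    pop: SimulatedPopulation,
    n_pool: int = 300,
    rng: np.random.Generator | int | None = None,
) -> tuple[SimulatedPopulation, np.ndarray]:
    """Draw a pool subsample without replacement.

    Returns the subsample and its true donor frequencies per locus
    (sum of dosages over 2*n_pool).
    """
    if n_pool > pop.n_individuals:
        raise ValueError("n_pool exceeds population size")
    rng = _as_rng(rng, fallback=0)
    idx = np.sort(rng.choice(pop.n_individuals, size=n_pool, replace=False))
    sub = pop.subset(idx)
    return sub, sub.donor_frequencies()


# ---------------------------------------------------------------------------
# Pooled reads

def simulate_pool_reads(
    loci: pd.DataFrame,
    model: PoolReadModel,
    rng: np.random.Generator | int | None = None,
) -> list[VariantSite]:
    """Draw pooled allelic depths per locus.

    ``loci`` needs columns chrom, pos, truth (donor frequency in the pool).
    Depth d ~ Poisson(mean_depth) (or fixed), donor reads ~ Binomial(d,
    truth); the REF allele carries the recurrent parent, ALT the donor.
    Zero-depth loci are emitted and left to downstream filters.
    """
    rng = _as_rng(rng, fallback=0)
    truth = np.asarray(loci["truth"], dtype=float)
    if np.any((truth < 0) | (truth > 1)):
        raise ValueError("truth frequencies must lie in [0, 1]")
    n = len(truth)
    if model.fixed_depth is not None:
        depth = np.full(n, int(model.fixed_depth))
    else:
        depth = rng.poisson(model.mean_depth, n)
    donor = rng.binomial(depth, truth)
    qual = synthetic_qual(depth)
    chroms = loci["chrom"].to_numpy()
    positions = loci["pos"].to_numpy()
    return [
        VariantSite(str(chroms[i]), int(positions[i]), model.ref_base,
                    model.alt_base, float(qual[i]),
                    int(depth[i] - donor[i]), int(donor[i]))
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# Marker linkage windows and pseudo-SNPs

def build_mlw(
    markers: pd.DataFrame | Sequence[MarkerRecord],
    genome: SimGenome,
    chrom_table: ChromosomeTable | None = None,
    extension_fraction: float = 0.45,
    gap_fraction: float = 0.10,
    min_size: int = 500,
    max_size: int = 1_000_000,
) -> tuple[list[HaplotypeWindow], pd.DataFrame]:
    """Marker linkage windows plus their pseudo-SNP grid.

    Markers are 1-bp anchors extended like genes, then size-filtered
    (default 500 bp to 1 Mb). Pseudo-SNP loci sit on the genome-wide
    ``pseudo_snp_spacing`` grid; those falling inside a window are
    annotated to it (they inherit the anchor marker's truth frequency, i.e.
    no intra-window recombination in the truth). Returns (windows, loci)
    where loci has columns chrom, pos, anchor_id, is_pseudo and contains
    each surviving window's anchor marker plus its pseudo-SNPs.
    """
    if isinstance(markers, pd.DataFrame):
        records = [MarkerRecord(str(r.marker_id), str(r.chrom), int(r.pos_bp),
                                None)
                   for r in markers.itertuples(index=False)]
    else:
        records = list(markers)
    table = chrom_table if chrom_table is not None else genome.chrom_table
    anchors = anchors_from_markers(records)
    anchors.sort(key=lambda a: (a.chrom, a.start))
    wins = extend_anchors(anchors, table, extension_fraction, gap_fraction)
    wins = filter_windows(wins, min_size, max_size)

    spacing = genome.pseudo_snp_spacing
    marker_pos = {(m.chrom, m.pos_bp) for m in records}
    rows = []
    for w in wins:
        rows.append((w.chrom, w.core_start, w.anchor_id, False))
        first = ((w.start + spacing - 1) // spacing) * spacing
        for pos in range(first, w.end + 1, spacing):
            if (w.chrom, pos) not in marker_pos:
                rows.append((w.chrom, pos, w.anchor_id, True))
    loci = pd.DataFrame(rows, columns=["chrom", "pos", "anchor_id",
                                       "is_pseudo"])
    loci = loci.sort_values(["chrom", "pos"], kind="mergesort",
                            ignore_index=True)
    return wins, loci


# ---------------------------------------------------------------------------
# Recovery experiment

def recovery_experiment(
    genome: SimGenome | None = None,
    scheme: CrossingScheme | None = None,
    n_pool: int = 300,
    model: PoolReadModel | None = None,
    coverage_thresholds: Sequence[int] = (0, 200, 500),
    seed: int = 0,
    n_population: int = 24_000,
    min_qual: float = 30.0,
    genome_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Coverage-vs-accuracy experiment for HAF estimation.

    Runs the full chain — population simulation, 300-genotype pool,
    Poisson/binomial read counts with pseudo-SNPs, MLW construction, SNP
    assignment, HAF aggregation — and reports Pearson r and RMSE between
    the estimates and the population's true donor frequencies: one row per
    minimum-total-reads threshold at HAF level plus one SNP-level row (all
    SNPs with at least one read, no aggregation).

    The pool reads are drawn from the subsample's frequencies while the
    reference is the full population, so the accuracy ceiling includes the
    subsampling error a real pooled experiment carries. All randomness
    derives from the single ``seed``.
    """
    rng = _as_rng(seed)
    if genome is None:
        genome = default_genome(rng, **(genome_kwargs or {}))
    if scheme is None:
        scheme = field_population_scheme()
    if model is None:
        model = PoolReadModel()

    pop = simulate_population(genome, scheme, n_population, rng)
    sub, truth_sub = sample_pool(pop, n_pool, rng)
    truth_pop = pop.donor_frequencies()

    marker_index = {
        (str(r.chrom), int(r.pos_bp)): i
        for i, r in enumerate(genome.markers.itertuples(index=False))
    }
    marker_id_index = {
        str(r.marker_id): i
        for i, r in enumerate(genome.markers.itertuples(index=False))
    }

    windows, loci = build_mlw(genome.markers, genome)
    anchor_idx = loci["anchor_id"].map(marker_id_index).to_numpy()
    loci = loci.assign(truth=truth_sub[anchor_idx],
                       truth_pop=truth_pop[anchor_idx])

    sites = simulate_pool_reads(loci, model, rng)
    parents = ParentalGenotypes({
        (str(c), int(p)): (model.alt_base, model.ref_base)
        for c, p in zip(loci["chrom"], loci["pos"])
    })

    kept = [s for s in sites if s.total_reads >= 1 and s.qual > min_qual]
    records, rejected = polarize_sites(kept, parents)
    if sum(rejected.values()):
        log.warning("recovery_experiment: %s sites rejected", rejected)

    truth_by_locus = {
        (c, int(p)): t
        for c, p, t in zip(loci["chrom"], loci["pos"], loci["truth_pop"])
    }
    snp_est = np.array([r.freq for r in records])
    snp_truth = np.array([truth_by_locus[(r.chrom, r.pos)] for r in records])

    assigned, _ = assign_snps(records, windows)
    window_truth = []
    hafs = []
    for w in windows:
        members = assigned[w]
        if not members:
            continue
        hafs.append(haplotype_allele_frequency(members, w))
        window_truth.append(truth_pop[marker_id_index[w.anchor_id]])
    window_truth = np.array(window_truth)
    haf_est = np.array([h.haf for h in hafs])
    haf_reads = np.array([h.total_reads for h in hafs])

    rows = [{
        "level": "snp", "min_total_reads": 1, "n": len(snp_est),
        "pearson_r": pearson_r(snp_est, snp_truth),
        "rmse": rmse(snp_est, snp_truth),
    }]
    for t in coverage_thresholds:
        sel = haf_reads > t
        n_sel = int(sel.sum())
        if n_sel < 3:
            rows.append({"level": "haf", "min_total_reads": t, "n": n_sel,
                         "pearson_r": float("nan"), "rmse": float("nan")})
            continue
        rows.append({
            "level": "haf", "min_total_reads": t, "n": n_sel,
            "pearson_r": pearson_r(haf_est[sel], window_truth[sel]),
            "rmse": rmse(haf_est[sel], window_truth[sel]),
        })
    return pd.DataFrame(rows, columns=["level", "min_total_reads", "n",
                                       "pearson_r", "rmse"])


# ---------------------------------------------------------------------------
# Fixture emission

def write_fixture_set(
    out_dir,
    genome: SimGenome | None = None,
    scheme: CrossingScheme | None = None,
    n_population: int = 24_000,
    n_pool: int = 300,
    model: PoolReadModel | None = None,
    seed: int = 0,
    header_comment: str | None = None,
    genome_kwargs: dict | None = None,
) -> dict[str, str]:
    """Emit a complete fixture set: pool VCF, parental/marker/chromosome
    tables and per-locus truth TSV. Returns the written paths."""
    from pathlib import Path

    from . import io_formats as iof

    rng = _as_rng(seed)
    if genome is None:
        genome = default_genome(rng, **(genome_kwargs or {}))
    if scheme is None:
        scheme = field_population_scheme()
    if model is None:
        model = PoolReadModel()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    pop = simulate_population(genome, scheme, n_population, rng)
    sub, truth_sub = sample_pool(pop, n_pool, rng)
    windows, loci = build_mlw(genome.markers, genome)
    marker_id_index = {
        str(r.marker_id): i
        for i, r in enumerate(genome.markers.itertuples(index=False))
    }
    anchor_idx = loci["anchor_id"].map(marker_id_index).to_numpy()
    loci = loci.assign(truth=truth_sub[anchor_idx])
    sites = simulate_pool_reads(loci, model, rng)

    paths = {
        "pool_vcf": str(out / "pool.vcf"),
        "parents": str(out / "parents.tsv"),
        "markers": str(out / "markers.tsv"),
        "chromosomes": str(out / "chromosomes.tsv"),
        "truth": str(out / "truth.tsv"),
        "windows": str(out / "windows.tsv"),
    }
    iof.write_vcf_sites(sites, genome.chrom_table, paths["pool_vcf"])
    parents = ParentalGenotypes({
        (str(c), int(p)): (model.alt_base, model.ref_base)
        for c, p in zip(loci["chrom"], loci["pos"])
    })
    iof.write_parental_tsv(parents, paths["parents"], header_comment)
    iof.write_marker_table(genome.marker_records(), paths["markers"],
                           header_comment)
    iof.write_chrom_table(genome.chrom_table, paths["chromosomes"])
    iof.write_windows_tsv(windows, paths["windows"], header_comment)
    with open(paths["truth"], "w") as fh:
        if header_comment:
            fh.write(f"#{header_comment}\n")
        loci.to_csv(fh, sep="\t", index=False, float_format="%.17g")
    return paths
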