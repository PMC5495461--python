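"""Synthetic data with planted, recorded structure.

The generator emulates the study design this pipeline targets: four pooled
small-RNA libraries from a callus-induction time course (uninduced control
CK and Stages I-III), siRNA duplex loci on a random genome, digital gene
expression counts for gene models, and MeDIP-style region-level methylation
signal.  Everything planted — duplex geometry, fold changes, siRNA→gene
cleavage links, 24-nt siRNA→methylation→gene links, expression-pattern
classes — is recorded in a :class:`GroundTruth` object so recall and
specificity of every downstream stage are measurable.

Noise model: tag and gene counts are negative binomial with a small
overdispersion (pooled single libraries without biological replicates are
dominated by counting noise, which is the regime the exact tag-count test
assumes); methylation signal is Poisson with lognormal multiplicative
noise on the mean.  All draws flow from one seed through per-component
child streams, so adding a component never perturbs the others.

Planted expression-pattern classes for linked target genes follow the
three callus-induction archetypes: class 1 sustained up-regulation,
class 2 sustained down-regulation, class 3 transient up-regulation in
Stage I with a return to baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import revcomp
from .io import (
    GeneModel,
    write_bed,
    write_class_annotation_gff3,
    write_fasta,
    write_genes_gff3,
    write_tsv,
)
from .stats import LIBRARIES

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "PlantedLocus",
    "SyntheticBundle",
    "SizingError",
    "PlacementError",
    "generate_genome",
    "plant_duplex_loci",
    "simulate_srna_libraries",
    "simulate_gene_expression",
    "simulate_methylation",
    "simulate_degradome",
    "simulate_annotation_map",
    "simulate_all",
    "write_bundle",
]

# fixed transcript architecture of simulated genes (nt)
UTR5_LEN, CDS_LEN, UTR3_LEN = 30, 99, 51
GENE_LEN = UTR5_LEN + CDS_LEN + UTR3_LEN
EXCL_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA", "miRNA")


class SizingError(ValueError):
    """The genome cannot hold the requested features."""


class PlacementError(RuntimeError):
    """Random placement failed after the retry budget."""


@dataclass
class SimulationConfig:
    genome_length: int = 300_000
    n_genes: int = 40
    n_duplex_loci: int = 60
    #: length distribution over 20-25 nt; 24-nt dominant, 22-nt second,
    #: matching the canonical plant siRNA size profile
    sirna_length_weights: dict[int, float] = field(
        default_factory=lambda: {20: 0.06, 21: 0.14, 22: 0.22, 23: 0.08, 24: 0.40, 25: 0.10}
    )
    n_24nt_loci: int = 16
    baseline_mean: float = 50.0
    dispersion: float = 0.001
    de_fraction: float = 0.5
    planted_lfc: float = 2.0
    n_cleavage_links: int = 12
    n_methyl_links: int = 8
    library_sizes: tuple[float, float, float, float] = (1e6, 1e6, 1e6, 1e6)
    noise_sd: float = 0.05
    ratio_planted: float = 4.0
    near_miss_fraction: float = 0.2
    n_decoy_tags: int = 20
    n_decoy_de_genes: int = 4
    n_background_regions: int = 30
    n_excluded_intervals: int = 10
    gene_baseline_mean: float = 200.0
    #: MeDIP-style region coverage; deep enough that a ratio_planted-fold
    #: drop (hypo-methylation) stays detectable by the exact count test
    region_baseline_mean: float = 50.0
    seed: int = 0

    def validate(self) -> None:
        counts = (
            self.genome_length,
            self.n_genes,
            self.n_duplex_loci,
            self.n_24nt_loci,
            self.n_cleavage_links,
            self.n_methyl_links,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be non-negative")
        if any(s <= 0 for s in self.library_sizes) or len(self.library_sizes) != 4:
            raise ValueError("library_sizes must be four positive depths")
        if self.planted_lfc <= 0:
            raise ValueError("planted_lfc must be positive")
        w = self.sirna_length_weights
        if set(w) - set(range(20, 26)) or abs(sum(w.values()) - 1.0) > 1e-9:
            raise ValueError("length weights must sum to 1 over lengths 20..25")
        if self.n_cleavage_links + self.n_methyl_links > self.n_genes:
            raise ValueError("more links than genes")


@dataclass
class PlantedLocus:
    locus_id: str
    kind: str  # duplex | near_miss | decoy_single
    chrom: str
    start: int  # genomic locus span, half-open
    end: int
    length: int  # siRNA length
    plus_tag_id: str | None
    minus_tag_id: str | None
    plus_seq: str | None
    minus_seq: str | None
    #: planted log2 fold change per stage (I, II, III); zeros = null locus
    lfc: tuple[float, float, float] = (0.0, 0.0, 0.0)
    link_mode: str | None = None  # cleavage | methyl | None
    linked_gene: str | None = None
    guide_tag_id: str | None = None
    pattern_class: int | None = None

    @property
    def is_de(self) -> bool:
        return any(v != 0 for v in self.lfc)

    def tag_ids(self) -> list[str]:
        return [t for t in (self.plus_tag_id, self.minus_tag_id) if t]


@dataclass
class GroundTruth:
    planted_loci: list[PlantedLocus]
    #: (guide tag id, gene id, transcript site span half-open)
    cleavage_links: list[tuple[str, str, tuple[int, int]]]
    #: (guide tag id, gene id, genomic region span, hyper|hypo)
    methyl_links: list[tuple[str, str, tuple[int, int], str]]
    cluster_labels: dict[str, int]
    decoy_de_genes: list[str] = field(default_factory=list)

    def loci_by_kind(self, kind: str) -> list[PlantedLocus]:
        return [p for p in self.planted_loci if p.kind == kind]


@dataclass
class SyntheticBundle:
    config: SimulationConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    excluded: list[tuple[str, int, int, str]]
    truth: GroundTruth
    tag_table: pd.DataFrame
    gene_table: pd.DataFrame
    region_table: pd.DataFrame  # chrom,start,end,region_id,gene_id,role
    region_signal: pd.DataFrame
    degradome: pd.DataFrame
    annotation_map: pd.DataFrame
    library_sizes: tuple[float, float, float, float]


# --- helpers -------------------------------------------------------------


def _child_rngs(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _nb_counts(rng: np.random.Generator, mean, dispersion: float):
    """Negative-binomial counts with Var = m + dispersion * m^2 (Poisson limit)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 1e-12:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def _place_interval(
    rng: np.random.Generator,
    length: int,
    genome_length: int,
    occupied: list[tuple[int, int]],
    max_retries: int = 2000,
) -> tuple[int, int]:
    for _ in range(max_retries):
        start = int(rng.integers(0, genome_length - length + 1))
        end = start + length
        if all(end <= s or start >= e for s, e in occupied):
            occupied.append((start, end))
            return start, end
    raise PlacementError(f"could not place a {length}-bp interval after {max_retries} tries")


# --- operations ----------------------------------------------------------


def generate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], list[GeneModel], list[tuple[str, int, int, str]]]:
    """Random genome with non-overlapping gene models and excluded-class intervals.

    Requires ``genome_length >= 10 * n_genes * mean gene length`` so that
    random placement of every downstream feature has room; raises
    :class:`SizingError` naming the deficit otherwise.
    """
    config.validate()
    required = 10 * config.n_genes * GENE_LEN
    if config.genome_length < max(required, GENE_LEN if config.n_genes else 1):
        raise SizingError(
            f"genome_length {config.genome_length} is too short for "
            f"{config.n_genes} genes: need at least {required} "
            f"(deficit {required - config.genome_length} bp)"
        )
    if rng is None:
        rng = _child_rngs(config.seed, ["genome"])["genome"]
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, config.genome_length)])
    genome = {"chr1": seq}

    genes: list[GeneModel] = []
    if config.n_genes:
        slack = config.genome_length - config.n_genes * GENE_LEN
        raw = np.sort(rng.choice(slack + 1, size=config.n_genes, replace=False))
        for i, r in enumerate(raw):
            start = int(r) + i * GENE_LEN
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    gene_id=f"gene{i + 1:04d}",
                    chrom="chr1",
                    start=start,
                    end=start + GENE_LEN,
                    strand=strand,
                    utr5_len=UTR5_LEN,
                    cds_len=CDS_LEN,
                    utr3_len=UTR3_LEN,
                )
            )

    occupied = [(g.start, g.end) for g in genes]
    excluded: list[tuple[str, int, int, str]] = []
    for i in range(config.n_excluded_intervals):
        s, e = _place_interval(rng, 80, config.genome_length, occupied)
        excluded.append(("chr1", s, e, EXCL_CLASSES[i % len(EXCL_CLASSES)]))
    return genome, genes, excluded


def _sample_length(rng: np.random.Generator, weights: dict[int, float]) -> int:
    lengths = sorted(weights)
    p = np.array([weights[l] for l in lengths], dtype=float)
    return int(rng.choice(lengths, p=p / p.sum()))


def plant_duplex_loci(
    genome: dict[str, str],
    genes: list[GeneModel],
    excluded: list[tuple[str, int, int, str]],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Plant duplex loci, link loci, near-miss pairs, and decoy tags.

    Cleavage-linked loci sit antisense inside a target gene's CDS (so the
    guide tag is perfectly complementary to the transcript); methylation-
    linked loci are 24-nt duplexes in a target gene's 3' UTR; background
    duplexes, near-miss pairs (overhang 3, failing the geometry) and
    single-stranded decoy tags occupy intergenic space away from the
    excluded-class annotation.
    """
    config.validate()
    if rng is None:
        rng = _child_rngs(config.seed, ["genome", "loci"])["loci"]
    chrom = "chr1"
    seq = genome[chrom]
    # planted loci must avoid excluded intervals; intergenic ones avoid genes too
    forbidden = [(s, e) for _, s, e, _ in excluded]
    occupied_intergenic = forbidden + [(g.start, g.end) for g in genes]

    loci: list[PlantedLocus] = []
    cleavage_links: list[tuple[str, str, tuple[int, int]]] = []
    methyl_links: list[tuple[str, str, tuple[int, int], str]] = []
    cluster_labels: dict[str, int] = {}
    tag_no = 0

    def new_tag_id() -> str:
        nonlocal tag_no
        tag_no += 1
        return f"p{tag_no:05d}"

    def duplex_from_span(start: int, length: int, kind: str, offset: int = 2) -> PlantedLocus:
        """Minus tag at [start, start+L), plus tag at [start+offset, ...)."""
        minus_seq = revcomp(seq[start : start + length])
        plus_seq = seq[start + offset : start + offset + length]
        return PlantedLocus(
            locus_id=f"loc{len(loci) + 1:04d}",
            kind=kind,
            chrom=chrom,
            start=start,
            end=start + offset + length,
            length=length,
            plus_tag_id=new_tag_id(),
            minus_tag_id=new_tag_id(),
            plus_seq=plus_seq,
            minus_seq=minus_seq,
        )

    lfc = config.planted_lfc
    # pattern class -> (gene lfc profile, siRNA lfc profile); anti-proportional
    patterns = {
        1: ((lfc, lfc, lfc), (-lfc, -lfc, -lfc)),
        2: ((-lfc, -lfc, -lfc), (lfc, lfc, lfc)),
        3: ((lfc, 0.0, 0.0), (-lfc, 0.0, 0.0)),
    }

    gene_pool = list(genes)
    rng.shuffle(gene_pool)
    if config.n_cleavage_links + config.n_methyl_links > len(gene_pool):
        raise SizingError("not enough genes to host the requested links")
    cleavage_genes = gene_pool[: config.n_cleavage_links]
    methyl_genes = gene_pool[
        config.n_cleavage_links : config.n_cleavage_links + config.n_methyl_links
    ]

    # cleavage-linked loci: guide antisense to the CDS, lengths 21/22 so the
    # 24-nt exclusion rule never fires on these genes
    for i, gene in enumerate(cleavage_genes):
        length = 21 if i % 2 == 0 else 22
        w = UTR5_LEN + int(rng.integers(0, CDS_LEN - length + 1))  # transcript site start
        site = (w, w + length)
        if gene.strand == "+":
            guide_gstart = gene.start + w  # guide maps '-' here
            locus_start = guide_gstart - 0  # minus tag at guide position
            loc = duplex_from_span(locus_start, length, "duplex")
            guide_id = loc.minus_tag_id
        else:
            # transcript window w maps to genomic [end-w-L, end-w); guide is '+'
            guide_gstart = gene.end - w - length
            locus_start = guide_gstart - 2  # plus tag must sit at guide position
            loc = duplex_from_span(locus_start, length, "duplex")
            guide_id = loc.plus_tag_id
        gene_prof, sirna_prof = patterns[(i % 3) + 1]
        loc.lfc = sirna_prof
        loc.link_mode = "cleavage"
        loc.linked_gene = gene.gene_id
        loc.guide_tag_id = guide_id
        loc.pattern_class = (i % 3) + 1
        loci.append(loc)
        cleavage_links.append((guide_id, gene.gene_id, site))
        cluster_labels[gene.gene_id] = (i % 3) + 1

    # methylation-linked loci: 24-nt duplexes in the 3' UTR
    for i, gene in enumerate(methyl_genes):
        length = 24
        direction = "hyper" if i % 4 != 3 else "hypo"  # mostly hyper, some hypo
        u3_start = UTR5_LEN + CDS_LEN
        w = u3_start + int(rng.integers(0, UTR3_LEN - length - 2 + 1))
        if gene.strand == "+":
            guide_gstart = gene.start + w
            locus_start = guide_gstart
            loc = duplex_from_span(locus_start, length, "duplex")
            guide_id = loc.minus_tag_id
        else:
            guide_gstart = gene.end - w - length
            locus_start = guide_gstart - 2
            loc = duplex_from_span(locus_start, length, "duplex")
            guide_id = loc.plus_tag_id
        sign = 1.0 if direction == "hyper" else -1.0
        loc.lfc = (sign * lfc, sign * lfc, sign * lfc)
        loc.link_mode = "methyl"
        loc.linked_gene = gene.gene_id
        loc.guide_tag_id = guide_id
        loc.pattern_class = 2 if direction == "hyper" else 1
        loci.append(loc)
        region = gene.utr3_genomic_span()
        methyl_links.append((guide_id, gene.gene_id, region, direction))
        cluster_labels[gene.gene_id] = loc.pattern_class

    # background duplex loci (intergenic); a de_fraction of them carry
    # planted fold changes with random direction, the rest are null
    n_background = max(config.n_duplex_loci - len(loci), 0)
    n_extra_24 = max(config.n_24nt_loci - sum(1 for p in loci if p.length == 24), 0)
    for i in range(n_background):
        if i < n_extra_24:
            length = 24
        else:
            length = _sample_length(rng, config.sirna_length_weights)
        s, _ = _place_interval(rng, length + 2, config.genome_length, occupied_intergenic)
        loc = duplex_from_span(s, length, "duplex")
        if rng.random() < config.de_fraction:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            stages_mask = rng.random(3) < 0.8  # DE in most stages
            if not stages_mask.any():
                stages_mask[0] = True
            loc.lfc = tuple(sign * lfc * m for m in stages_mask)
        loci.append(loc)

    # near-miss pairs: overhang of 3 bases, violating the duplex geometry
    n_near = int(round(config.near_miss_fraction * config.n_duplex_loci))
    for _ in range(n_near):
        length = _sample_length(rng, config.sirna_length_weights)
        s, _ = _place_interval(rng, length + 3, config.genome_length, occupied_intergenic)
        loc = duplex_from_span(s, length, "near_miss", offset=3)
        loci.append(loc)

    # single-stranded decoy tags; half of them carry planted fold changes so
    # specificity of the link filters (not just the duplex caller) is testable
    for i in range(config.n_decoy_tags):
        length = _sample_length(rng, config.sirna_length_weights)
        s, _ = _place_interval(rng, length, config.genome_length, occupied_intergenic)
        loc = PlantedLocus(
            locus_id=f"loc{len(loci) + 1:04d}",
            kind="decoy_single",
            chrom=chrom,
            start=s,
            end=s + length,
            length=length,
            plus_tag_id=new_tag_id(),
            minus_tag_id=None,
            plus_seq=seq[s : s + length],
            minus_seq=None,
        )
        if i % 2 == 0:
            loc.lfc = (lfc, lfc, lfc)
        loci.append(loc)

    decoy_gene_pool = gene_pool[config.n_cleavage_links + config.n_methyl_links :]
    decoy_de_genes = [g.gene_id for g in decoy_gene_pool[: config.n_decoy_de_genes]]

    return GroundTruth(
        planted_loci=loci,
        cleavage_links=cleavage_links,
        methyl_links=methyl_links,
        cluster_labels=cluster_labels,
        decoy_de_genes=decoy_de_genes,
    )


def simulate_srna_libraries(
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Tag-count table over the four libraries.

    Each planted tag's library mean is ``baseline_mean`` scaled by the
    library depth, times 2**(planted log2 fold change) in flagged stages;
    counts are negative binomial with the configured dispersion.  Both
    strands of a duplex share the locus profile.
    """
    config.validate()
    if rng is None:
        rng = _child_rngs(config.seed, ["genome", "loci", "srna"])["srna"]
    depth_scale = np.asarray(config.library_sizes, dtype=float) / 1e6
    rows = []
    for loc in truth.planted_loci:
        mult = np.array([1.0] + [2.0**v for v in loc.lfc])
        means = config.baseline_mean * depth_scale * mult
        for tag_id, seq_ in ((loc.plus_tag_id, loc.plus_seq), (loc.minus_tag_id, loc.minus_seq)):
            if tag_id is None:
                continue
            counts = _nb_counts(rng, means, config.dispersion)
            rows.append(
                dict(
                    tag_id=tag_id,
                    sequence=seq_,
                    len=loc.length,
                    count_CK=int(counts[0]),
                    count_I=int(counts[1]),
                    count_II=int(counts[2]),
                    count_III=int(counts[3]),
                )
            )
    return pd.DataFrame(
        rows, columns=["tag_id", "sequence", "len", "count_CK", "count_I", "count_II", "count_III"]
    )


def _gene_lfc_profiles(truth: GroundTruth, config: SimulationConfig) -> dict[str, np.ndarray]:
    """Planted gene log2FC profile (Stages I-III vs CK) per linked/decoy gene."""
    lfc = config.planted_lfc
    class_profiles = {
        1: np.array([lfc, lfc, lfc]),
        2: np.array([-lfc, -lfc, -lfc]),
        3: np.array([lfc, 0.0, 0.0]),
    }
    out: dict[str, np.ndarray] = {}
    for loc in truth.planted_loci:
        if loc.linked_gene is not None:
            out[loc.linked_gene] = -np.asarray(loc.lfc, dtype=float)
    for gid, cls in truth.cluster_labels.items():
        out.setdefault(gid, class_profiles[cls])
    for gid in truth.decoy_de_genes:
        out[gid] = np.array([lfc, lfc, lfc])
    return out


def simulate_gene_expression(
    genes: list[GeneModel],
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Gene count table whose linked genes move opposite to their siRNAs.

    A gene linked to a siRNA receives stage means anti-proportional to the
    siRNA's planted profile (noiseless profile correlation exactly -1);
    unlinked genes are stationary; a few recorded decoy genes are planted
    differentially expressed without any siRNA link.
    """
    config.validate()
    if rng is None:
        rng = _child_rngs(config.seed, ["genome", "loci", "srna", "gene"])["gene"]
    known = {g.gene_id for g in genes}
    for links, label in ((truth.cleavage_links, "cleavage"), (truth.methyl_links, "methyl")):
        for link in links:
            if link[1] not in known:
                raise ValueError(f"{label} link references unknown gene {link[1]}")
    profiles = _gene_lfc_profiles(truth, config)
    depth_scale = np.asarray(config.library_sizes, dtype=float) / 1e6
    rows = []
    for g in genes:
        prof = profiles.get(g.gene_id, np.zeros(3))
        mult = np.concatenate([[1.0], 2.0**prof])
        means = config.gene_baseline_mean * depth_scale * mult
        counts = _nb_counts(rng, means, config.dispersion)
        rows.append(
            dict(
                gene_id=g.gene_id,
                count_CK=int(counts[0]),
                count_I=int(counts[1]),
                count_II=int(counts[2]),
                count_III=int(counts[3]),
            )
        )
    return pd.DataFrame(rows, columns=["gene_id", "count_CK", "count_I", "count_II", "count_III"])


def simulate_methylation(
    genes: list[GeneModel],
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Region table (BED-style) plus per-library methylation signal counts.

    Hyper-methylated links multiply the linked region's stage means by
    ``ratio_planted``; hypo links divide; background regions (one per
    unlinked gene, up to ``n_background_regions``, plus a few sub-threshold
    regions) stay stationary.  Counts are Poisson with lognormal noise on
    the mean.
    """
    config.validate()
    if rng is None:
        rng = _child_rngs(config.seed, ["genome", "loci", "srna", "gene", "methyl"])["methyl"]
    by_id = {g.gene_id: g for g in genes}
    depth_scale = np.asarray(config.library_sizes, dtype=float) / 1e6

    regions = []
    signal_rows = []
    planted_dirs: dict[str, str] = {}

    def add_region(region_id, chrom, start, end, gene_id, role, mean_scale, ratios):
        regions.append(
            dict(chrom=chrom, start=start, end=end, name=region_id, score=0, strand=".",
                 gene_id=gene_id, role=role)
        )
        means = config.region_baseline_mean * mean_scale * depth_scale * ratios
        noisy = means * rng.lognormal(0.0, config.noise_sd, size=4)
        counts = rng.poisson(noisy)
        signal_rows.append(
            dict(region_id=region_id, count_CK=int(counts[0]), count_I=int(counts[1]),
                 count_II=int(counts[2]), count_III=int(counts[3]))
        )

    for i, (sirna_id, gene_id, span, direction) in enumerate(truth.methyl_links):
        gene = by_id.get(gene_id)
        if gene is None:
            raise ValueError(f"methyl link references unknown gene {gene_id}")
        start, end = span
        if start < gene.start or end > gene.end:
            raise PlacementError(f"region {span} outside gene {gene_id} span")
        r = config.ratio_planted if direction == "hyper" else 1.0 / config.ratio_planted
        ratios = np.array([1.0, r, r, r])
        rid = f"mr{i + 1:04d}"
        planted_dirs[rid] = direction
        add_region(rid, gene.chrom, start, end, gene_id, "3'UTR", 1.0, ratios)

    linked = {gid for _, gid, _, _ in truth.methyl_links}
    background_genes = [g for g in genes if g.gene_id not in linked]
    for j, gene in enumerate(background_genes[: config.n_background_regions]):
        start, end = gene.utr3_genomic_span()
        add_region(f"bg{j + 1:04d}", gene.chrom, start, end, gene.gene_id, "3'UTR",
                   1.0, np.ones(4))
    # sub-threshold regions: mean signal below the 0.25-RPM screen
    for j, gene in enumerate(background_genes[config.n_background_regions :][:3]):
        start, end = gene.utr3_genomic_span()
        low_scale = 0.1 / max(config.region_baseline_mean, 1e-9)
        add_region(f"low{j + 1:04d}", gene.chrom, start, end, gene.gene_id, "3'UTR",
                   low_scale, np.ones(4))

    region_table = pd.DataFrame(regions)
    signal = pd.DataFrame(
        signal_rows, columns=["region_id", "count_CK", "count_I", "count_II", "count_III"]
    )
    return region_table, signal


def simulate_degradome(
    genes: list[GeneModel],
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-transcript 5'-end counts with a peak at each planted cleavage site.

    The peak sits at the transcript base opposite guide position 10 (the
    5' end of the downstream slicing fragment); background positions get
    sparse low counts.
    """
    if rng is None:
        rng = _child_rngs(
            config.seed, ["genome", "loci", "srna", "gene", "methyl", "degradome"]
        )["degradome"]
    by_id = {g.gene_id: g for g in genes}
    rows = []
    for sirna_id, gene_id, (w, w_end) in truth.cleavage_links:
        gene = by_id[gene_id]
        length = w_end - w
        peak_pos = w + length - 10  # 0-based transcript coordinate
        tlen = gene.length
        cover = {int(p): 1 + int(rng.poisson(1)) for p in rng.integers(0, tlen, size=15)}
        cover[peak_pos] = 50 + int(rng.poisson(10))
        for pos in sorted(cover):
            rows.append(dict(transcript_id=gene_id, position=pos, count=cover[pos]))
    return pd.DataFrame(rows, columns=["transcript_id", "position", "count"])


def simulate_annotation_map(
    genes: list[GeneModel],
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Gene -> functional-term map with one term enriched per planted cluster."""
    if rng is None:
        rng = _child_rngs(
            config.seed, ["genome", "loci", "srna", "gene", "methyl", "degradome", "annot"]
        )["annot"]
    terms = {
        1: ("T:0001", "sustained induction response"),
        2: ("T:0002", "repression-associated activity"),
        3: ("T:0003", "transient stimulus response"),
    }
    rows = []
    for gid, cls in truth.cluster_labels.items():
        if rng.random() < 0.8:
            term_id, term_name = terms[cls]
            rows.append(dict(gene_id=gid, term_id=term_id, term_name=term_name))
    for g in genes:
        if rng.random() < 0.15:
            rows.append(dict(gene_id=g.gene_id, term_id="T:0099", term_name="background process"))
    return pd.DataFrame(rows, columns=["gene_id", "term_id", "term_name"]).drop_duplicates()


def simulate_all(config: SimulationConfig) -> SyntheticBundle:
    """Run every generator component off one seed and bundle the results."""
    rngs = _child_rngs(
        config.seed, ["genome", "loci", "srna", "gene", "methyl", "degradome", "annot"]
    )
    genome, genes, excluded = generate_genome(config, rngs["genome"])
    truth = plant_duplex_loci(genome, genes, excluded, config, rngs["loci"])
    tag_table = simulate_srna_libraries(truth, config, rngs["srna"])
    gene_table = simulate_gene_expression(genes, truth, config, rngs["gene"])
    region_table, region_signal = simulate_methylation(genes, truth, config, rngs["methyl"])
    degradome = simulate_degradome(genes, truth, config, rngs["degradome"])
    annotation_map = simulate_annotation_map(genes, truth, config, rngs["annot"])
    return SyntheticBundle(
        config=config,
        genome=genome,
        genes=genes,
        excluded=excluded,
        truth=truth,
        tag_table=tag_table,
        gene_table=gene_table,
        region_table=region_table,
        region_signal=region_signal,
        degradome=degradome,
        annotation_map=annotation_map,
        library_sizes=config.library_sizes,
    )


def write_bundle(bundle: SyntheticBundle, outdir) -> dict[str, Path]:
    """Write every simulated input in its standard on-disk format."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "genes": outdir / "genes.gff3",
        "excluded": outdir / "excluded_classes.gff3",
        "tags": outdir / "tag_counts.tsv",
        "gene_counts": outdir / "gene_counts.tsv",
        "regions": outdir / "methyl_regions.bed",
        "region_signal": outdir / "methyl_signal.tsv",
        "degradome": outdir / "degradome.tsv",
        "annotation_map": outdir / "annotation_map.tsv",
        "library_sizes": outdir / "library_sizes.tsv",
        "truth_loci": outdir / "truth_loci.tsv",
        "truth_links": outdir / "truth_links.tsv",
    }
    write_fasta(bundle.genome, paths["genome"])
    write_genes_gff3(bundle.genes, paths["genes"])
    write_class_annotation_gff3(bundle.excluded, paths["excluded"])
    write_tsv(bundle.tag_table, paths["tags"])
    write_tsv(bundle.gene_table, paths["gene_counts"])
    write_bed(bundle.region_table[["chrom", "start", "end", "name", "score", "strand"]],
              paths["regions"])
    write_tsv(bundle.region_table, outdir / "methyl_regions_full.tsv")
    write_tsv(bundle.region_signal, paths["region_signal"])
    write_tsv(bundle.degradome, paths["degradome"])
    write_tsv(bundle.annotation_map, paths["annotation_map"])
    write_tsv(
        pd.DataFrame(
            dict(library=list(LIBRARIES), total=list(bundle.library_sizes))
        ),
        paths["library_sizes"],
    )
    loci_rows = [
        dict(
            locus_id=p.locus_id, kind=p.kind, chrom=p.chrom, start=p.start, end=p.end,
            length=p.length, plus_tag_id=p.plus_tag_id or "", minus_tag_id=p.minus_tag_id or "",
            lfc_I=p.lfc[0], lfc_II=p.lfc[1], lfc_III=p.lfc[2],
            link_mode=p.link_mode or "", linked_gene=p.linked_gene or "",
            guide_tag_id=p.guide_tag_id or "", pattern_class=p.pattern_class or 0,
        )
        for p in bundle.truth.planted_loci
    ]
    write_tsv(pd.DataFrame(loci_rows), paths["truth_loci"])
    link_rows = [
        dict(mode="cleavage", sirna_id=s, gene_id=g, start=span[0], end=span[1], direction="")
        for s, g, span in bundle.truth.cleavage_links
    ] + [
        dict(mode="methyl", sirna_id=s, gene_id=g, start=span[0], end=span[1], direction=d)
        for s, g, span, d in bundle.truth.methyl_links
    ]
    write_tsv(pd.DataFrame(link_rows), paths["truth_links"])
    return paths
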