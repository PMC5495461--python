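"""End-to-end orchestration: catalog -> duplexes -> DE -> targets -> clusters.

One configuration drives every stage; each stage writes its table under the
output directory and records its row counts and output checksums in a run
manifest, so a full run is reproducible (identical inputs, config and seed
give byte-identical outputs) and resumable (stages whose outputs already
exist are reloaded instead of recomputed when ``resume`` is set).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .catalog import (
    SiRNADuplex,
    SRNATag,
    TagAlignment,
    call_duplexes,
    map_tags,
    subtract_annotated_classes,
    tags_from_table,
)
from .cluster import PatternProfile, hypergeometric_enrichment, kmeans_profiles
from .io import (
    read_bed,
    read_class_annotation_gff3,
    read_fasta,
    read_genes_gff3,
    read_tsv,
    sha256_file,
    write_bed,
    write_tsv,
)
from .simulate import SimulationConfig, simulate_all, write_bundle
from .stats import STAGES, CountProfile, DECall, call_de, normalize_rpm
from .targets import (
    MethylRegionCall,
    TargetSite,
    call_methyl_regions,
    find_target_sites,
    select_cleavage_targets,
    select_methylation_targets,
    validate_cleavage_with_degradome,
)

log = logging.getLogger(__name__)

COUNT_COLS = ["count_CK", "count_I", "count_II", "count_III"]


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    simulate: SimulationConfig | None = None
    #: input paths; filled automatically when ``simulate`` is set
    inputs: dict[str, str] = field(default_factory=dict)
    resume: bool = False
    # catalog / duplex thresholds
    min_len: int = 18
    max_len: int = 30
    min_support: int = 5
    min_overlap: int | None = 15
    # differential expression
    sirna_p: float = 0.01
    sirna_lfc: float = 1.0
    gene_q: float = 0.001
    gene_lfc: float = 1.0
    pseudocount: float = 0.5
    # target association
    max_penalty: float = 4.0
    corr_thresh: float = -0.4
    exclude_24nt: str = "de"
    methyl_q: float = 0.05
    methyl_signal: float = 0.25
    methyl_ratio: float = 2.0
    # clustering / enrichment
    k: int = 3
    restarts: int = 50
    enrich_p: float = 0.05


@dataclass
class RunManifest:
    version: str
    config: dict
    stages: list[dict] = field(default_factory=list)

    def add(self, name: str, outputs: dict[str, str], counts: dict, seconds: float) -> None:
        self.stages.append(
            dict(name=name, outputs=outputs, counts=counts, seconds=round(seconds, 3))
        )

    @property
    def checksums(self) -> dict[str, str]:
        out = {}
        for st in self.stages:
            out.update(st["outputs"])
        return out

    def counts(self, stage: str) -> dict:
        for st in self.stages:
            if st["name"] == stage:
                return st["counts"]
        raise KeyError(stage)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


# --- stage (de)serialization --------------------------------------------


def _de_to_df(calls: list[DECall]) -> pd.DataFrame:
    return pd.DataFrame([asdict(c) for c in calls])


def _de_from_df(df: pd.DataFrame) -> list[DECall]:
    return [DECall(**{**row, "feature_id": str(row["feature_id"])})
            for row in df.to_dict("records")]


def _sites_to_df(sites: list[TargetSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                sirna_id=s.sirna_id,
                gene_id=s.gene_id,
                strand_targeted=s.transcript_strand_targeted,
                start=s.site_span[0],
                end=s.site_span[1],
                region=s.region,
                penalty=s.penalty,
            )
            for s in sites
        ],
        columns=["sirna_id", "gene_id", "strand_targeted", "start", "end", "region", "penalty"],
    )


def _sites_from_df(df: pd.DataFrame) -> list[TargetSite]:
    return [
        TargetSite(
            sirna_id=str(r["sirna_id"]),
            gene_id=str(r["gene_id"]),
            transcript_strand_targeted=str(r["strand_targeted"]),
            site_span=(int(r["start"]), int(r["end"])),
            region=str(r["region"]),
            penalty=float(r["penalty"]),
        )
        for r in df.to_dict("records")
    ]


def _methyl_to_df(calls: list[MethylRegionCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = dict(region_id=c.region_id, gene_id=c.gene_id, role=c.region_role)
        for lib, v in zip(["CK", "I", "II", "III"], c.rpm):
            row[f"rpm_{lib}"] = v
        for stage in STAGES:
            row[f"q_{stage}"] = c.q[stage]
            row[f"ratio_{stage}"] = c.ratio[stage]
            row[f"direction_{stage}"] = c.direction[stage]
        rows.append(row)
    return pd.DataFrame(rows)


def _methyl_from_df(df: pd.DataFrame) -> list[MethylRegionCall]:
    calls = []
    for r in df.to_dict("records"):
        call = MethylRegionCall(
            region_id=str(r["region_id"]),
            gene_id="" if pd.isna(r["gene_id"]) else str(r["gene_id"]),
            region_role=str(r["role"]),
            rpm=np.array([r[f"rpm_{lib}"] for lib in ["CK", "I", "II", "III"]]),
        )
        for stage in STAGES:
            call.q[stage] = float(r[f"q_{stage}"])
            call.ratio[stage] = float(r[f"ratio_{stage}"])
            call.direction[stage] = str(r[f"direction_{stage}"])
        calls.append(call)
    return calls


def _interactions_to_df(interactions) -> pd.DataFrame:
    rows = []
    for it in interactions:
        site = it.site
        rows.append(
            dict(
                sirna_id=it.sirna_id,
                gene_id=it.gene_id,
                mode=it.mode,
                site=(f"{site.site_span[0]}-{site.site_span[1]}:{site.region}"
                      if isinstance(site, TargetSite) else str(site)),
                corr_sirna_gene=it.corr_sirna_gene,
                corr_methyl_gene=it.corr_methyl_gene,
                stages_supported=",".join(it.stages_supported),
                methyl_direction=it.methyl_direction,
                both_strands=it.both_strands,
            )
        )
    cols = ["sirna_id", "gene_id", "mode", "site", "corr_sirna_gene", "corr_methyl_gene",
            "stages_supported", "methyl_direction", "both_strands"]
    return pd.DataFrame(rows, columns=cols)


# --- the pipeline --------------------------------------------------------


class Pipeline:
    """Stage-by-stage runner; every stage is also callable on its own."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        cfg_snapshot = asdict(config)
        self.manifest = RunManifest(version=__version__, config=cfg_snapshot)

    # -- helpers

    def _stage(self, name, outputs, counts, t0):
        checks = {str(Path(p).name): sha256_file(p) for p in outputs}
        self.manifest.add(name, checks, counts, time.perf_counter() - t0)

    def _resumable(self, *paths) -> bool:
        return self.config.resume and all(Path(p).exists() for p in paths)

    # -- stages

    def run(self) -> RunManifest:
        cfg = self.config
        if cfg.simulate is None:
            required = {"genome", "genes", "excluded", "tags", "gene_counts",
                        "library_sizes"}
            missing = required - set(cfg.inputs)
            if missing:
                raise ValueError(
                    "config must provide a simulate block or input paths; "
                    f"missing inputs: {sorted(missing)}"
                )
        if cfg.simulate is not None:
            t0 = time.perf_counter()
            simdir = self.outdir / "sim"
            expected = simdir / "tag_counts.tsv"
            if not self._resumable(expected):
                bundle = simulate_all(cfg.simulate)
                paths = write_bundle(bundle, simdir)
            else:
                paths = {p.stem: p for p in simdir.iterdir()}
            cfg.inputs = {
                "genome": str(simdir / "genome.fa"),
                "genes": str(simdir / "genes.gff3"),
                "excluded": str(simdir / "excluded_classes.gff3"),
                "tags": str(simdir / "tag_counts.tsv"),
                "gene_counts": str(simdir / "gene_counts.tsv"),
                "regions": str(simdir / "methyl_regions_full.tsv"),
                "region_signal": str(simdir / "methyl_signal.tsv"),
                "degradome": str(simdir / "degradome.tsv"),
                "annotation_map": str(simdir / "annotation_map.tsv"),
                "library_sizes": str(simdir / "library_sizes.tsv"),
            }
            self._stage("simulate", cfg.inputs.values(), {}, t0)

        genome = read_fasta(cfg.inputs["genome"])
        genes = read_genes_gff3(cfg.inputs["genes"])
        totals = read_tsv(cfg.inputs["library_sizes"])["total"].to_numpy(dtype=float)

        tags, alignments = self.stage_catalog(genome)
        duplexes = self.stage_duplex(tags, alignments)
        sirna_de = self.stage_de_sirna(tags, duplexes, totals)
        gene_table = read_tsv(cfg.inputs["gene_counts"])
        gene_de = self.stage_de_gene(gene_table, totals)
        sites = self.stage_sites(tags, sirna_de, genes, genome)

        tag_by_id = {t.tag_id: t for t in tags}
        sirna_rpm = {
            t.tag_id: normalize_rpm(t.counts, totals) for t in tags
        }
        gene_rpm = {
            str(r["gene_id"]): normalize_rpm(
                np.array([r[c] for c in COUNT_COLS], dtype=float), totals
            )
            for r in gene_table.to_dict("records")
        }
        sirna_lengths = {t.tag_id: t.length for t in tags}

        cleavage = self.stage_cleavage(sirna_de, sites, gene_de, sirna_rpm, gene_rpm,
                                       sirna_lengths)
        self.stage_degradome(cleavage)

        methyl_inputs = {"regions", "region_signal"} <= set(cfg.inputs)
        if methyl_inputs:
            methyl_calls = self.stage_methyl_regions(totals)
            methylation = self.stage_methyl_targets(
                sirna_de, sites, methyl_calls, gene_de, sirna_rpm, gene_rpm, sirna_lengths
            )
        else:
            log.info("methylation inputs missing; skipping methylation stages")
            methylation = []

        clusters = self.stage_cluster(cleavage, methylation, gene_de)
        self.stage_enrich(clusters, gene_table)

        self.manifest.write(self.outdir / "manifest.json")
        return self.manifest

    def stage_catalog(self, genome):
        t0 = time.perf_counter()
        cfg = self.config
        cat_path = self.outdir / "catalog.tsv"
        aln_path = self.outdir / "alignments.bed"
        if self._resumable(cat_path, aln_path):
            cat = read_tsv(cat_path)
            tags = tags_from_table(
                cat[["tag_id", "sequence", *COUNT_COLS]].itertuples(index=False)
            )
            for t, hc in zip(tags, cat["hit_count"]):
                t.hit_count = int(hc)
            bed = read_bed(aln_path)
            alignments = [
                TagAlignment(str(r["name"]), str(r["chrom"]), int(r["start"]),
                             int(r["end"]), str(r["strand"]))
                for r in bed.to_dict("records")
            ]
            self._stage("catalog", [cat_path, aln_path], dict(tags=len(tags)), t0)
            return tags, alignments
        tag_df = read_tsv(cfg.inputs["tags"])
        keep = (tag_df["len"] >= cfg.min_len) & (tag_df["len"] <= cfg.max_len)
        tag_df = tag_df[keep]
        tags = tags_from_table(
            tag_df[["tag_id", "sequence", *COUNT_COLS]].itertuples(index=False)
        )
        tags, alignments = map_tags(tags, genome)
        annotation = read_class_annotation_gff3(cfg.inputs["excluded"])
        tags, alignments = subtract_annotated_classes(tags, alignments, annotation)
        cat = pd.DataFrame(
            [
                dict(tag_id=t.tag_id, sequence=t.sequence, len=t.length,
                     **dict(zip(COUNT_COLS, (int(v) for v in t.counts))),
                     hit_count=t.hit_count)
                for t in tags
            ]
        )
        write_tsv(cat, cat_path)
        bed = pd.DataFrame(
            [
                dict(chrom=a.chrom, start=a.start, end=a.end, name=a.tag_id,
                     score=next(t.hit_count for t in tags if t.tag_id == a.tag_id),
                     strand=a.strand)
                for a in alignments
            ]
        )
        write_bed(bed, aln_path)
        self._stage("catalog", [cat_path, aln_path],
                    dict(tags=len(tags), alignments=len(alignments)), t0)
        return tags, alignments

    def stage_duplex(self, tags, alignments):
        t0 = time.perf_counter()
        cfg = self.config
        path = self.outdir / "duplexes.tsv"
        bed_path = self.outdir / "duplex_loci.bed"
        if self._resumable(path):
            df = read_tsv(path)
            duplexes = []
            for r in df.to_dict("records"):
                d = SiRNADuplex(
                    duplex_id=str(r["duplex_id"]),
                    plus=TagAlignment(str(r["plus_tag"]), str(r["chrom"]),
                                      int(r["plus_start"]), int(r["plus_end"]), "+"),
                    minus=TagAlignment(str(r["minus_tag"]), str(r["chrom"]),
                                       int(r["minus_start"]), int(r["minus_end"]), "-"),
                )
                d.support = int(r["support"])
                duplexes.append(d)
            self._stage("duplex", [path, bed_path], dict(duplexes=len(duplexes)), t0)
            return duplexes
        duplexes = call_duplexes(alignments, tags, cfg.min_support, cfg.min_overlap)
        df = pd.DataFrame(
            [
                dict(duplex_id=d.duplex_id, chrom=d.locus[0],
                     locus_start=d.locus[1], locus_end=d.locus[2],
                     plus_tag=d.plus.tag_id, plus_start=d.plus.start, plus_end=d.plus.end,
                     minus_tag=d.minus.tag_id, minus_start=d.minus.start,
                     minus_end=d.minus.end, support=d.support)
                for d in duplexes
            ],
            columns=["duplex_id", "chrom", "locus_start", "locus_end", "plus_tag",
                     "plus_start", "plus_end", "minus_tag", "minus_start", "minus_end",
                     "support"],
        )
        write_tsv(df, path)
        bed = pd.DataFrame(
            [dict(chrom=d.locus[0], start=d.locus[1], end=d.locus[2],
                  name=d.duplex_id, score=d.support, strand=".") for d in duplexes]
        )
        write_bed(bed if len(bed) else pd.DataFrame(columns=["chrom"]), bed_path)
        self._stage("duplex", [path, bed_path], dict(duplexes=len(duplexes)), t0)
        return duplexes

    def stage_de_sirna(self, tags, duplexes, totals):
        t0 = time.perf_counter()
        cfg = self.config
        path = self.outdir / "de_sirna.tsv"
        if self._resumable(path):
            calls = _de_from_df(read_tsv(path))
        else:
            duplex_tags = {d.plus.tag_id for d in duplexes} | {d.minus.tag_id for d in duplexes}
            profiles = [
                CountProfile(t.tag_id, "sirna", t.counts,
                             normalize_rpm(t.counts, totals))
                for t in tags
                if t.tag_id in duplex_tags
            ]
            calls = call_de(profiles, totals, mode="sirna", p_thresh=cfg.sirna_p,
                            lfc_thresh=cfg.sirna_lfc, pseudocount=cfg.pseudocount)
            write_tsv(_de_to_df(calls), path)
        n_de = {s: sum(1 for c in calls if c.direction != "ns"
                       and c.comparison.split("_vs_")[0] == s) for s in STAGES}
        self._stage("de_sirna", [path], dict(calls=len(calls), de_per_stage=n_de), t0)
        return calls

    def stage_de_gene(self, gene_table, totals):
        t0 = time.perf_counter()
        cfg = self.config
        path = self.outdir / "de_gene.tsv"
        if self._resumable(path):
            calls = _de_from_df(read_tsv(path))
        else:
            profiles = [
                CountProfile(str(r["gene_id"]), "gene",
                             np.array([r[c] for c in COUNT_COLS], dtype=float),
                             normalize_rpm(np.array([r[c] for c in COUNT_COLS],
                                                    dtype=float), totals))
                for r in gene_table.to_dict("records")
            ]
            calls = call_de(profiles, totals, mode="gene", p_thresh=cfg.gene_q,
                            lfc_thresh=cfg.gene_lfc, pseudocount=cfg.pseudocount)
            write_tsv(_de_to_df(calls), path)
        n_de = {s: sum(1 for c in calls if c.direction != "ns"
                       and c.comparison.split("_vs_")[0] == s) for s in STAGES}
        self._stage("de_gene", [path], dict(calls=len(calls), de_per_stage=n_de), t0)
        return calls

    def stage_sites(self, tags, sirna_de, genes, genome):
        t0 = time.perf_counter()
        cfg = self.config
        path = self.outdir / "target_sites.tsv"
        if self._resumable(path):
            sites = _sites_from_df(read_tsv(path))
        else:
            de_ids = {c.feature_id for c in sirna_de if c.direction != "ns"}
            # scan DE siRNAs plus every cataloged 24-nt tag (needed for the
            # 24-nt exclusion rule even when those tags are not DE)
            scan_ids = de_ids | {t.tag_id for t in tags if t.length == 24}
            seqs = {t.tag_id: t.sequence for t in tags if t.tag_id in scan_ids}
            sites = find_target_sites(seqs, genes, genome, cfg.max_penalty)
            write_tsv(_sites_to_df(sites), path)
        self._stage("sites", [path], dict(sites=len(sites)), t0)
        return sites

    def stage_cleavage(self, sirna_de, sites, gene_de, sirna_rpm, gene_rpm, sirna_lengths):
        t0 = time.perf_counter()
        cfg = self.config
        path = self.outdir / "interactions_cleavage.tsv"
        interactions = select_cleavage_targets(
            sirna_de, sites, gene_de, sirna_rpm, gene_rpm, sirna_lengths,
            corr_thresh=cfg.corr_thresh, exclude_24nt=cfg.exclude_24nt,
        )
        write_tsv(_interactions_to_df(interactions), path)
        self._stage("cleavage_targets", [path], dict(interactions=len(interactions)), t0)
        return interactions

    def stage_degradome(self, cleavage):
        t0 = time.perf_counter()
        path = self.outdir / "degradome_validation.tsv"
        if "degradome" not in self.config.inputs:
            return []
        degradome = read_tsv(self.config.inputs["degradome"])
        records = [
            validate_cleavage_with_degradome(it.site, degradome)
            for it in cleavage
            if isinstance(it.site, TargetSite)
        ]
        df = pd.DataFrame(
            [
                dict(sirna_id=r.sirna_id, gene_id=r.gene_id, predicted_pos=r.predicted_pos,
                     peak_pos=-1 if r.peak_pos is None else r.peak_pos,
                     peak_count=r.peak_count, confirmed=r.confirmed)
                for r in records
            ],
            columns=["sirna_id", "gene_id", "predicted_pos", "peak_pos", "peak_count",
                     "confirmed"],
        )
        write_tsv(df, path)
        self._stage("degradome", [path],
                    dict(validated=sum(r.confirmed for r in records), total=len(records)), t0)
        return records

    def stage_methyl_regions(self, totals):
        t0 = time.perf_counter()
        cfg = self.config
        path = self.outdir / "methyl_region_calls.tsv"
        if self._resumable(path):
            calls = _methyl_from_df(read_tsv(path))
        else:
            signal = read_tsv(cfg.inputs["region_signal"])
            regions = read_tsv(cfg.inputs["regions"])
            calls = call_methyl_regions(
                signal, regions, totals, q_thresh=cfg.methyl_q,
                min_signal_rpm=cfg.methyl_signal, min_ratio=cfg.methyl_ratio,
            )
            write_tsv(_methyl_to_df(calls), path)
        n_sig = sum(
            1 for c in calls if any(d != "ns" for d in c.direction.values())
        )
        self._stage("methyl_regions", [path], dict(regions=len(calls), changed=n_sig), t0)
        return calls

    def stage_methyl_targets(self, sirna_de, sites, methyl_calls, gene_de, sirna_rpm,
                             gene_rpm, sirna_lengths):
        t0 = time.perf_counter()
        cfg = self.config
        path = self.outdir / "interactions_methylation.tsv"
        methyl_rpm_by_gene = {c.gene_id: c.rpm for c in methyl_calls if c.gene_id}
        interactions = select_methylation_targets(
            sirna_de, sites, methyl_calls, gene_de, sirna_rpm, gene_rpm,
            methyl_rpm_by_gene, sirna_lengths, corr_thresh=cfg.corr_thresh,
        )
        write_tsv(_interactions_to_df(interactions), path)
        self._stage("methyl_targets", [path],
                    dict(interactions=len(interactions),
                         both_strands=sum(i.both_strands for i in interactions)), t0)
        return interactions

    def stage_cluster(self, cleavage, methylation, gene_de):
        t0 = time.perf_counter()
        cfg = self.config
        path = self.outdir / "clusters.tsv"
        target_genes = sorted({i.gene_id for i in cleavage} | {i.gene_id for i in methylation})
        lfc = {}
        for c in gene_de:
            stage = c.comparison.split("_vs_")[0]
            lfc.setdefault(c.feature_id, {})[stage] = c.log2fc
        profiles = [
            PatternProfile(g, np.array([lfc[g][s] for s in STAGES])) for g in target_genes
            if g in lfc
        ]
        if len(profiles) >= cfg.k and cfg.k >= 1:
            profiles, centroids = kmeans_profiles(profiles, k=cfg.k, seed=cfg.seed,
                                                  restarts=cfg.restarts)
        else:
            log.info("too few target genes to cluster (%d)", len(profiles))
            centroids = np.zeros((0, 3))
        df = pd.DataFrame(
            [
                dict(gene_id=p.gene_id, cluster=p.cluster or 0,
                     lfc_I=p.features[0], lfc_II=p.features[1], lfc_III=p.features[2])
                for p in profiles
            ],
            columns=["gene_id", "cluster", "lfc_I", "lfc_II", "lfc_III"],
        )
        write_tsv(df, path)
        sizes = df["cluster"].value_counts().to_dict() if len(df) else {}
        self._stage("cluster", [path],
                    dict(genes=len(profiles),
                         cluster_sizes={int(k): int(v) for k, v in sizes.items()}), t0)
        return profiles

    def stage_enrich(self, profiles, gene_table):
        t0 = time.perf_counter()
        cfg = self.config
        path = self.outdir / "enrichment.tsv"
        if "annotation_map" not in cfg.inputs:
            return []
        ann = read_tsv(cfg.inputs["annotation_map"])
        annotation = {}
        names = {}
        for r in ann.to_dict("records"):
            annotation.setdefault(str(r["gene_id"]), set()).add(str(r["term_id"]))
            names[str(r["term_id"])] = str(r["term_name"])
        background = {str(g) for g in gene_table["gene_id"]}
        results = []
        for cl in sorted({p.cluster for p in profiles if p.cluster}):
            cluster_genes = {p.gene_id for p in profiles if p.cluster == cl}
            results.extend(
                hypergeometric_enrichment(cluster_genes, background, annotation,
                                          term_names=names, p_thresh=cfg.enrich_p,
                                          cluster=cl)
            )
        df = pd.DataFrame(
            [
                dict(cluster=r.cluster, term_id=r.term_id, term_name=r.term_name,
                     k_in=r.k_in, n_cluster=r.n_cluster, K_in=r.K_in, N_bg=r.N_bg,
                     p=r.p, q=r.q, significant=r.significant)
                for r in results
            ],
            columns=["cluster", "term_id", "term_name", "k_in", "n_cluster", "K_in",
                     "N_bg", "p", "q", "significant"],
        )
        write_tsv(df, path)
        self._stage("enrich", [path],
                    dict(terms=len(results),
                         significant=sum(r.significant for r in results)), t0)
        return results


def run_pipeline(config: PipelineConfig) -> RunManifest:
    return Pipeline(config).run()
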