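"""Linking differentially expressed siRNAs to their target genes.

Two association routes are implemented.

Cleavage route: a DE-siRNA with a complementarity site on a gene's sense
strand (its transcript) directs slicing.  Sites come from an ungapped,
position-weighted penalty scan (mismatch 1.0, G:U wobble 0.5, doubled over
guide positions 2-13 from the siRNA 5' end — the seed-proximal core that
dominates plant target recognition).  A (siRNA, gene) pair survives only
when the siRNA is differentially expressed, the gene carries no 24-nt
siRNA sense-strand site, the gene itself is differentially expressed, and
the two expression profiles are anti-correlated (Pearson < -0.4 on
log2(RPM + 0.5) over the four libraries).

Methylation route: 24-nt DE-siRNAs direct DNA methylation of matching
loci.  A 24-nt siRNA with a site on either strand of a gene is linked when
the gene's methylation region changes concordantly (siRNA up with
hyper-methylation and transcript down, or the mirror pattern) and both the
methylation signal and the siRNA are anti-correlated with the transcript.

Degradome validation: slicing leaves the 3' fragment's 5' end opposite
guide positions 10/11; a degradome 5'-end peak exactly there, dominant
within +/-20 nt, confirms a predicted site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import revcomp
from .io import GeneModel
from .stats import STAGES, ac_pvalue, bh_adjust, log_profile, normalize_rpm, profile_correlation

__all__ = [
    "TargetSite",
    "TargetInteraction",
    "MethylRegionCall",
    "DegradomeValidation",
    "score_complementarity",
    "find_target_sites",
    "select_cleavage_targets",
    "call_methyl_regions",
    "select_methylation_targets",
    "validate_cleavage_with_degradome",
]

_CODE = {c: i for i, c in enumerate("ACGT")}

# pairing penalty between an siRNA base (row) and the transcript base it
# faces (column): Watson-Crick 0, G:U wobble 0.5, mismatch 1
_BASE_PENALTY = np.ones((4, 4))
for _s, _t in (("A", "T"), ("C", "G"), ("G", "C"), ("T", "A")):
    _BASE_PENALTY[_CODE[_s], _CODE[_t]] = 0.0
_BASE_PENALTY[_CODE["G"], _CODE["T"]] = 0.5
_BASE_PENALTY[_CODE["T"], _CODE["G"]] = 0.5

CORE_POSITIONS = range(2, 14)  # guide positions 2..13, 1-based from the 5' end


@dataclass
class TargetSite:
    sirna_id: str
    gene_id: str
    transcript_strand_targeted: str  # sense | antisense
    site_span: tuple[int, int]  # transcript coordinates, half-open, sense space
    region: str  # 5'UTR | CDS | 3'UTR
    penalty: float


@dataclass
class TargetInteraction:
    sirna_id: str
    gene_id: str
    mode: str  # cleavage | methylation
    site: TargetSite | str  # TargetSite (cleavage) or region id (methylation)
    corr_sirna_gene: float
    corr_methyl_gene: float = float("nan")
    stages_supported: tuple[str, ...] = ()
    methyl_direction: str = "na"  # hyper | hypo | na
    both_strands: bool = False


@dataclass
class MethylRegionCall:
    region_id: str
    gene_id: str
    region_role: str
    rpm: np.ndarray  # per library
    q: dict[str, float] = field(default_factory=dict)
    ratio: dict[str, float] = field(default_factory=dict)
    direction: dict[str, str] = field(default_factory=dict)  # hyper | hypo | ns


@dataclass
class DegradomeValidation:
    sirna_id: str
    gene_id: str
    predicted_pos: int  # 0-based transcript position of the downstream 5' end
    peak_pos: int | None
    peak_count: int
    confirmed: bool


def _encode(seq: str) -> np.ndarray:
    seq = seq.upper().replace("U", "T")
    try:
        return np.array([_CODE[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"non-nucleotide character in sequence: {exc}") from exc


def score_complementarity(
    sirna_sequence: str, transcript_sequence: str, max_penalty: float = 4.0
) -> list[tuple[int, int, float]]:
    """Ungapped complementarity scan of a siRNA against a transcript.

    Slides the siRNA (antiparallel) along the transcript and scores each
    window: per-position penalty 1.0 for a mismatch, 0.5 for a G:U wobble,
    doubled when the guide position (1-based from the siRNA 5' end) falls
    in the 2-13 core.  Returns (start, end, penalty) transcript windows
    with penalty <= max_penalty; empty when the siRNA is longer than the
    transcript.
    """
    s = _encode(sirna_sequence)
    t = _encode(transcript_sequence)
    L = s.size
    if L > t.size:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(t, L)  # (n_windows, L)
    # transcript window column i faces guide position L-i (1-based)
    guide_pos = L - np.arange(L)
    weights = np.where((guide_pos >= 2) & (guide_pos <= 13), 2.0, 1.0)
    col_pen = _BASE_PENALTY[s[::-1][None, :], windows]  # s reversed aligns with columns
    penalties = (col_pen * weights).sum(axis=1)
    hits = np.nonzero(penalties <= max_penalty)[0]
    return [(int(w), int(w) + L, float(penalties[w])) for w in hits]


def cleavage_position(site_start: int, sirna_len: int) -> int:
    """0-based transcript position opposite guide base 10: the 5' end of the
    downstream slicing fragment."""
    return site_start + sirna_len - 10


def find_target_sites(
    sirna_seqs: dict[str, str],
    genes: list[GeneModel],
    genome: dict[str, str],
    max_penalty: float = 4.0,
) -> list[TargetSite]:
    """All complementarity sites of the given siRNAs on every gene, both strands.

    Site spans are reported in sense-transcript coordinates regardless of
    the strand targeted; the annotated region (5'UTR/CDS/3'UTR) is taken at
    the site midpoint.
    """
    sites: list[TargetSite] = []
    for gene in genes:
        transcript = gene.transcript_seq(genome)
        anti = revcomp(transcript)
        tlen = len(transcript)
        for sirna_id, seq in sirna_seqs.items():
            for start, end, pen in score_complementarity(seq, transcript, max_penalty):
                sites.append(
                    TargetSite(
                        sirna_id=sirna_id,
                        gene_id=gene.gene_id,
                        transcript_strand_targeted="sense",
                        site_span=(start, end),
                        region=gene.transcript_region((start + end) // 2),
                        penalty=pen,
                    )
                )
            for start, end, pen in score_complementarity(seq, anti, max_penalty):
                s_sense, e_sense = tlen - end, tlen - start
                sites.append(
                    TargetSite(
                        sirna_id=sirna_id,
                        gene_id=gene.gene_id,
                        transcript_strand_targeted="antisense",
                        site_span=(s_sense, e_sense),
                        region=gene.transcript_region((s_sense + e_sense) // 2),
                        penalty=pen,
                    )
                )
    return sites


def _de_stage_map(de_calls) -> dict[str, dict[str, str]]:
    """feature -> {stage: up|down} over significant calls only."""
    out: dict[str, dict[str, str]] = {}
    for call in de_calls:
        if call.direction != "ns":
            stage = call.comparison.split("_vs_")[0]
            out.setdefault(call.feature_id, {})[stage] = call.direction
    return out


def select_cleavage_targets(
    sirna_de_calls,
    target_sites: list[TargetSite],
    gene_de_calls,
    sirna_rpm: dict[str, np.ndarray],
    gene_rpm: dict[str, np.ndarray],
    sirna_lengths: dict[str, int],
    corr_thresh: float = -0.4,
    exclude_24nt: str = "de",
) -> list[TargetInteraction]:
    """The cleavage-route filter chain.

    Keeps (siRNA, gene) pairs where the siRNA is DE in at least one stage,
    a site hits the gene's sense strand, no 24-nt siRNA (the DE set by
    default, every cataloged one with ``exclude_24nt='all'``) has a
    sense-strand site on that gene, the gene is DE, and the siRNA/gene
    profile correlation is below ``corr_thresh``.
    """
    if exclude_24nt not in ("de", "all"):
        raise ValueError("exclude_24nt must be 'de' or 'all'")
    sirna_de = _de_stage_map(sirna_de_calls)
    gene_de = _de_stage_map(gene_de_calls)
    known_genes = set(gene_rpm)
    for site in target_sites:
        if site.gene_id not in known_genes:
            raise ValueError(f"site references unknown gene {site.gene_id}")

    def is_excluded_24(sirna_id: str) -> bool:
        if sirna_lengths.get(sirna_id) != 24:
            return False
        return True if exclude_24nt == "all" else sirna_id in sirna_de

    genes_with_24_sense = {
        s.gene_id
        for s in target_sites
        if s.transcript_strand_targeted == "sense" and is_excluded_24(s.sirna_id)
    }

    interactions: list[TargetInteraction] = []
    seen: set[tuple[str, str]] = set()
    for site in target_sites:
        if site.transcript_strand_targeted != "sense":
            continue
        sid, gid = site.sirna_id, site.gene_id
        if (sid, gid) in seen:
            continue
        if sid not in sirna_de:
            continue
        if gid in genes_with_24_sense:
            continue
        if gid not in gene_de:
            continue
        corr = profile_correlation(log_profile(sirna_rpm[sid]), log_profile(gene_rpm[gid]))
        if not (corr < corr_thresh):
            continue
        seen.add((sid, gid))
        stages = tuple(s for s in STAGES if s in sirna_de[sid] and s in gene_de[gid])
        interactions.append(
            TargetInteraction(
                sirna_id=sid,
                gene_id=gid,
                mode="cleavage",
                site=site,
                corr_sirna_gene=corr,
                stages_supported=stages,
            )
        )
    return interactions


def call_methyl_regions(
    region_signal: pd.DataFrame,
    region_table: pd.DataFrame,
    library_totals,
    q_thresh: float = 0.05,
    min_signal_rpm: float = 0.25,
    min_ratio: float = 2.0,
    rpm_floor: float = 0.01,
) -> list[MethylRegionCall]:
    """Differential-methylation screen on region-level signal counts.

    Per region and stage: exact tag-count p-value against CK, BH-adjusted
    across regions, then the three calling criteria — q below ``q_thresh``,
    mean signal above ``min_signal_rpm`` RPM in at least one library, and a
    direction-agnostic CK/stage ratio above ``min_ratio`` (RPM floored at
    ``rpm_floor`` to avoid division by zero).  Direction is hyper when the
    stage signal exceeds CK.
    """
    totals = np.asarray(library_totals, dtype=float)
    counts = region_signal[["count_CK", "count_I", "count_II", "count_III"]].to_numpy()
    rpm = normalize_rpm(counts, totals)
    meta = region_table.set_index("name") if "name" in region_table.columns else None
    calls = []
    for i, region_id in enumerate(region_signal["region_id"]):
        gene_id, role = "", ""
        if meta is not None and region_id in meta.index:
            gene_id = str(meta.loc[region_id].get("gene_id", ""))
            role = str(meta.loc[region_id].get("role", ""))
        calls.append(
            MethylRegionCall(region_id=str(region_id), gene_id=gene_id, region_role=role,
                             rpm=rpm[i])
        )
    signal_ok = (rpm > min_signal_rpm).any(axis=1)
    for j, stage in enumerate(STAGES, start=1):
        p = np.atleast_1d(ac_pvalue(counts[:, 0], counts[:, j], totals[0], totals[j]))
        q = bh_adjust(p)
        floored_ck = np.maximum(rpm[:, 0], rpm_floor)
        floored_st = np.maximum(rpm[:, j], rpm_floor)
        ratio = np.maximum(floored_st / floored_ck, floored_ck / floored_st)
        for i, call in enumerate(calls):
            call.q[stage] = float(q[i])
            call.ratio[stage] = float(ratio[i])
            significant = q[i] < q_thresh and signal_ok[i] and ratio[i] > min_ratio
            if not significant:
                call.direction[stage] = "ns"
            else:
                call.direction[stage] = "hyper" if rpm[i, j] > rpm[i, 0] else "hypo"
    return calls


#: concordant (siRNA direction, methylation direction, gene direction) patterns
CONCORDANT_PATTERNS = {("up", "hyper", "down"), ("down", "hypo", "up")}


def select_methylation_targets(
    sirna_de_calls,
    target_sites: list[TargetSite],
    methyl_calls: list[MethylRegionCall],
    gene_de_calls,
    sirna_rpm: dict[str, np.ndarray],
    gene_rpm: dict[str, np.ndarray],
    methyl_rpm_by_gene: dict[str, np.ndarray],
    sirna_lengths: dict[str, int],
    corr_thresh: float = -0.4,
) -> list[TargetInteraction]:
    """The RNA-directed-DNA-methylation association route.

    Links a 24-nt DE-siRNA to a gene when the siRNA has a site on either
    strand of the gene and, in at least one stage, the signs are concordant
    (siRNA up, region hyper-methylated, transcript down — or the mirror),
    with both corr(gene, methylation) and corr(gene, siRNA) below
    ``corr_thresh``.  Genes whose both strands carry a site from the same
    siRNA are flagged.
    """
    sirna_de = _de_stage_map(sirna_de_calls)
    gene_de = _de_stage_map(gene_de_calls)
    methyl_by_gene: dict[str, MethylRegionCall] = {}
    for call in methyl_calls:
        if call.gene_id:
            methyl_by_gene.setdefault(call.gene_id, call)

    pair_strands: dict[tuple[str, str], set[str]] = {}
    gene_strands: dict[str, set[str]] = {}
    for site in target_sites:
        if sirna_lengths.get(site.sirna_id) != 24 or site.sirna_id not in sirna_de:
            continue
        pair_strands.setdefault((site.sirna_id, site.gene_id), set()).add(
            site.transcript_strand_targeted
        )
        gene_strands.setdefault(site.gene_id, set()).add(site.transcript_strand_targeted)

    site_by_pair = {}
    for site in target_sites:
        site_by_pair.setdefault((site.sirna_id, site.gene_id), site)

    interactions: list[TargetInteraction] = []
    for (sid, gid), strands in sorted(pair_strands.items()):
        call = methyl_by_gene.get(gid)
        if call is None or gid not in gene_rpm:
            continue
        gene_dirs = gene_de.get(gid, {})
        concordant = [
            stage
            for stage in STAGES
            if (
                sirna_de[sid].get(stage),
                call.direction.get(stage, "ns"),
                gene_dirs.get(stage),
            )
            in CONCORDANT_PATTERNS
        ]
        if not concordant:
            continue
        corr_sg = profile_correlation(log_profile(sirna_rpm[sid]), log_profile(gene_rpm[gid]))
        corr_mg = profile_correlation(
            log_profile(gene_rpm[gid]), log_profile(methyl_rpm_by_gene[gid])
        )
        if not (corr_sg < corr_thresh and corr_mg < corr_thresh):
            continue
        direction = call.direction[concordant[0]]
        interactions.append(
            TargetInteraction(
                sirna_id=sid,
                gene_id=gid,
                mode="methylation",
                site=call.region_id,
                corr_sirna_gene=corr_sg,
                corr_methyl_gene=corr_mg,
                stages_supported=tuple(concordant),
                methyl_direction=direction,
                both_strands=gene_strands.get(gid, set()) >= {"sense", "antisense"},
            )
        )
    return interactions


def validate_cleavage_with_degradome(
    site: TargetSite, degradome: pd.DataFrame, window: int = 20
) -> DegradomeValidation:
    """Check a predicted site against degradome 5'-end evidence.

    Confirms when the 5'-end count at the predicted cleavage position
    (opposite guide positions 10/11) is positive and is the maximum within
    ``window`` nt on either side.  Transcripts without coverage are simply
    unconfirmed.
    """
    start, end = site.site_span
    predicted = cleavage_position(start, end - start)
    cov = degradome[degradome["transcript_id"] == site.gene_id]
    if cov.empty:
        return DegradomeValidation(site.sirna_id, site.gene_id, predicted, None, 0, False)
    near = cov[(cov["position"] >= predicted - window) & (cov["position"] <= predicted + window)]
    if near.empty:
        return DegradomeValidation(site.sirna_id, site.gene_id, predicted, None, 0, False)
    peak_row = near.loc[near["count"].idxmax()]
    at_pred = near[near["position"] == predicted]
    pred_count = int(at_pred["count"].sum())
    others = near[near["position"] != predicted]["count"]
    # the predicted position must strictly dominate the window, so flat or
    # tied coverage never confirms
    confirmed = pred_count > 0 and (others.empty or pred_count > int(others.max()))
    peak_pos = predicted if confirmed else int(peak_row["position"])
    return DegradomeValidation(
        site.sirna_id, site.gene_id, predicted, peak_pos, int(near["count"].max()), confirmed
    )
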