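"""Recovery and specificity metrics against the generator's ground truth.

Every metric compares a pipeline stage's output with the planted record:
duplex calling against planted loci and near-miss pairs, differential
calls against planted fold changes, and both association routes against
the planted siRNA-gene links.  Decoys are pairs the generator never
planted — a link is credited when the called pair involves any tag of the
planted locus and its linked gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .catalog import SiRNADuplex
from .simulate import GroundTruth
from .stats import STAGES

__all__ = [
    "DuplexRecovery",
    "DERecovery",
    "LinkRecovery",
    "duplex_recovery",
    "de_recovery",
    "link_recovery",
]


@dataclass
class DuplexRecovery:
    n_planted: int
    n_recovered: int
    n_near_miss_called: int
    n_unplanted_called: int

    @property
    def recall(self) -> float:
        return self.n_recovered / self.n_planted if self.n_planted else float("nan")


@dataclass
class DERecovery:
    n_true: int
    n_true_called: int
    n_null: int
    n_null_called: int

    @property
    def recall(self) -> float:
        return self.n_true_called / self.n_true if self.n_true else float("nan")

    @property
    def null_rate(self) -> float:
        return self.n_null_called / self.n_null if self.n_null else float("nan")


@dataclass
class LinkRecovery:
    n_planted: int
    n_recovered: int
    n_decoy: int

    @property
    def recall(self) -> float:
        return self.n_recovered / self.n_planted if self.n_planted else float("nan")


def duplex_recovery(
    duplexes: list[SiRNADuplex],
    truth: GroundTruth,
    tag_counts: dict[str, np.ndarray] | None = None,
    min_support: int = 5,
) -> DuplexRecovery:
    """Match called duplexes to planted loci by their tag-id pair.

    Only planted loci whose simulated counts clear the support threshold
    count toward recall (``tag_counts`` supplies the realized counts; if
    omitted, every planted duplex locus counts).
    """
    called_pairs = {(d.plus.tag_id, d.minus.tag_id) for d in duplexes}
    planted_pairs = set()
    for loc in truth.loci_by_kind("duplex"):
        if tag_counts is not None:
            support = max(
                int(tag_counts[t].max()) for t in loc.tag_ids() if t in tag_counts
            )
            if support <= min_support:
                continue
        planted_pairs.add((loc.plus_tag_id, loc.minus_tag_id))
    near_tags = {
        t for loc in truth.loci_by_kind("near_miss") for t in loc.tag_ids()
    }
    n_near_called = sum(
        1 for p, m in called_pairs if p in near_tags or m in near_tags
    )
    n_recovered = len(planted_pairs & called_pairs)
    n_unplanted = len(called_pairs - planted_pairs)
    return DuplexRecovery(
        n_planted=len(planted_pairs),
        n_recovered=n_recovered,
        n_near_miss_called=n_near_called,
        n_unplanted_called=n_unplanted,
    )


def de_recovery(de_calls, truth: GroundTruth, eligible_tags: set[str] | None = None) -> DERecovery:
    """siRNA-level differential-call recovery against planted fold changes.

    A planted-DE tag is credited when it is called in at least one of its
    planted stages with the planted direction; a null tag counts as a
    false call when flagged in any stage.
    """
    called: dict[str, dict[str, str]] = {}
    for c in de_calls:
        if c.direction != "ns":
            called.setdefault(c.feature_id, {})[c.comparison.split("_vs_")[0]] = c.direction
    n_true = n_true_called = n_null = n_null_called = 0
    for loc in truth.planted_loci:
        for tag in loc.tag_ids():
            if eligible_tags is not None and tag not in eligible_tags:
                continue
            if loc.is_de:
                n_true += 1
                want = {
                    stage: ("up" if v > 0 else "down")
                    for stage, v in zip(STAGES, loc.lfc)
                    if v != 0
                }
                got = called.get(tag, {})
                if any(got.get(stage) == d for stage, d in want.items()):
                    n_true_called += 1
            else:
                n_null += 1
                if tag in called:
                    n_null_called += 1
    return DERecovery(n_true, n_true_called, n_null, n_null_called)


def link_recovery(interactions, truth: GroundTruth, mode: str) -> LinkRecovery:
    """Planted-link recovery for one association route.

    ``mode`` is ``cleavage`` or ``methyl``.  A planted link is recovered
    when any reported interaction pairs a tag of the planted locus with the
    linked gene; any reported pair not explained by a planted locus-gene
    link is a decoy.
    """
    if mode == "cleavage":
        planted = {(s, g) for s, g, _ in truth.cleavage_links}
    else:
        planted = {(s, g) for s, g, _, _ in truth.methyl_links}
    # a locus's two tags are interchangeable evidence for its link
    locus_pairs = set()
    by_tag = {}
    for loc in truth.planted_loci:
        for t in loc.tag_ids():
            by_tag[t] = loc
    for s, g in planted:
        loc = by_tag[s]
        for t in loc.tag_ids():
            locus_pairs.add((t, g))

    reported = {(i.sirna_id, i.gene_id) for i in interactions}
    recovered = {
        (s, g) for s, g in planted
        if any((t, g) in reported for t in by_tag[s].tag_ids())
    }
    decoys = reported - locus_pairs
    return LinkRecovery(
        n_planted=len(planted), n_recovered=len(recovered), n_decoy=len(decoys)
    )
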