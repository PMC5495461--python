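"""From raw small-RNA reads to a catalog of genome-anchored siRNA duplexes.

The pipeline here mirrors the standard plant small-RNA workflow: collapse
identical reads to distinct tags with per-library counts, map tags to the
genome requiring perfect matches on either strand, discard tags touching
structural-RNA annotation (rRNA, tRNA, snRNA, snoRNA, miRNA), then call
siRNA duplexes as opposite-strand tag pairs showing the Dicer signature —
a 2-nt 3' overhang at both ends of the double-stranded region.

For two perfectly matching reads at one locus (plus strand at [ps, pe),
minus strand at [ms, me), 0-based half-open), the 2-nt 3' overhang on both
ends reduces to the two offset equations

    ps - ms == 2   and   pe - me == 2

because complementarity over the paired region is automatic when both tags
match the same genomic sequence exactly.  A duplex is reported only when at
least one of its two tags has more than ``min_support`` raw reads in at
least one library (strict: the default 5 means a count of 6 or more).
"""

from __future__ import annotations

import bisect
import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "SRNATag",
    "TagAlignment",
    "SiRNADuplex",
    "collapse_and_filter_reads",
    "map_tags",
    "subtract_annotated_classes",
    "call_duplexes",
    "revcomp",
    "EXCLUDED_CLASSES",
]

EXCLUDED_CLASSES = frozenset({"rRNA", "tRNA", "snRNA", "snoRNA", "miRNA"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SRNATag:
    """A distinct small-RNA sequence with per-library raw counts."""

    tag_id: str
    sequence: str  # 5'->3', DNA alphabet (U already mapped to T)
    counts: np.ndarray  # raw reads in CK, I, II, III
    hit_count: int = 0  # perfect-match genomic loci, filled by map_tags
    rpm: np.ndarray | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TagAlignment:
    """One perfect-match placement of a tag on the genome."""

    tag_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str  # '+' or '-'


@dataclass
class SiRNADuplex:
    duplex_id: str
    plus: TagAlignment
    minus: TagAlignment
    locus: tuple[str, int, int] = field(init=False)
    support: int = 0  # max raw count of either tag over the four libraries

    def __post_init__(self) -> None:
        self.locus = (
            self.plus.chrom,
            min(self.plus.start, self.minus.start),
            max(self.plus.end, self.minus.end),
        )


def _clean_sequence(seq: str) -> str | None:
    s = seq.strip().upper().replace("U", "T")
    if not s or any(c not in "ACGT" for c in s):
        return None
    return s


def collapse_and_filter_reads(
    reads_per_library: dict[str, list[str]],
    min_len: int = 18,
    max_len: int = 30,
    libraries: tuple[str, ...] = ("CK", "I", "II", "III"),
) -> list[SRNATag]:
    """Collapse identical read sequences into tags with per-library counts.

    Reads shorter than ``min_len`` (default 18 nt) or longer than
    ``max_len`` are dropped; U is mapped to T; records containing other
    non-nucleotide characters are rejected and counted in the log.
    Tags are returned in deterministic order (by descending total count,
    then sequence).
    """
    counts: dict[str, np.ndarray] = defaultdict(lambda: np.zeros(len(libraries), dtype=int))
    rejected = 0
    for lib_idx, lib in enumerate(libraries):
        for read in reads_per_library.get(lib, []):
            s = _clean_sequence(read)
            if s is None:
                rejected += 1
                continue
            if not (min_len <= len(s) <= max_len):
                continue
            counts[s][lib_idx] += 1
    if rejected:
        log.warning("rejected %d reads with non-nucleotide characters", rejected)
    ordered = sorted(counts.items(), key=lambda kv: (-int(kv[1].sum()), kv[0]))
    return [
        SRNATag(tag_id=f"tag{i + 1:06d}", sequence=seq, counts=c)
        for i, (seq, c) in enumerate(ordered)
    ]


def tags_from_table(rows) -> list[SRNATag]:
    """Build tags from an iterable of (tag_id, sequence, 4 counts) records."""
    tags = []
    for tag_id, seq, *c in rows:
        s = _clean_sequence(seq)
        if s is None:
            raise ValueError(f"tag {tag_id} has a non-nucleotide sequence")
        tags.append(SRNATag(tag_id=str(tag_id), sequence=s, counts=np.asarray(c, dtype=int)))
    return tags


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def map_tags(tags: list[SRNATag], genome: dict[str, str]) -> tuple[list[SRNATag], list[TagAlignment]]:
    """Exact-match mapping of every tag to both genome strands.

    Every occurrence is reported; tags with zero hits are dropped from the
    catalog (and logged).  Each retained tag records its total number of
    genomic hits so downstream users can filter multi-mappers.
    """
    genome_upper = {c: s.upper() for c, s in genome.items()}
    mapped_tags: list[SRNATag] = []
    alignments: list[TagAlignment] = []
    unmapped = 0
    for tag in tags:
        tag_hits: list[TagAlignment] = []
        rc = revcomp(tag.sequence)
        for chrom, seq in genome_upper.items():
            for start in _find_all(seq, tag.sequence):
                tag_hits.append(TagAlignment(tag.tag_id, chrom, start, start + tag.length, "+"))
            for start in _find_all(seq, rc):
                tag_hits.append(TagAlignment(tag.tag_id, chrom, start, start + tag.length, "-"))
        if not tag_hits:
            unmapped += 1
            continue
        tag.hit_count = len(tag_hits)
        mapped_tags.append(tag)
        alignments.extend(tag_hits)
    if unmapped:
        log.info("%d tags had no perfect genomic match and were dropped", unmapped)
    alignments.sort(key=lambda a: (a.chrom, a.start, a.end, a.strand, a.tag_id))
    return mapped_tags, alignments


def subtract_annotated_classes(
    tags: list[SRNATag],
    alignments: list[TagAlignment],
    class_annotation: list[tuple[str, int, int, str]],
) -> tuple[list[SRNATag], list[TagAlignment]]:
    """Remove tags whose alignments touch excluded structural-RNA classes.

    ``class_annotation`` holds (chrom, start, end, class) intervals,
    0-based half-open.  Any overlap of one base or more removes the whole
    tag — all of its alignments — from the catalog.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for chrom, start, end, cls in class_annotation:
        if cls not in EXCLUDED_CLASSES:
            raise ValueError(f"unknown excluded class {cls!r}")
        by_chrom[chrom].append((int(start), int(end)))
    for ivs in by_chrom.values():
        ivs.sort()

    def overlaps(aln: TagAlignment) -> bool:
        ivs = by_chrom.get(aln.chrom, [])
        starts = [s for s, _ in ivs]
        hi = bisect.bisect_left(starts, aln.end)  # intervals starting before aln.end
        return any(e > aln.start for _, e in ivs[:hi])

    bad_tags = {a.tag_id for a in alignments if overlaps(a)}
    kept_tags = [t for t in tags if t.tag_id not in bad_tags]
    kept_alns = [a for a in alignments if a.tag_id not in bad_tags]
    if bad_tags:
        log.info("removed %d tags overlapping excluded annotation", len(bad_tags))
    return kept_tags, kept_alns


def call_duplexes(
    alignments: list[TagAlignment],
    tags: list[SRNATag],
    min_support: int = 5,
    min_overlap: int | None = 15,
) -> list[SiRNADuplex]:
    """Pair opposite-strand alignments showing 2-nt 3' overhangs on both ends.

    A (plus, minus) pair on one chromosome is a duplex when
    ``plus.start - minus.start == 2`` and ``plus.end - minus.end == 2`` and
    the larger per-library raw count of the two tags exceeds
    ``min_support`` (strict).  ``min_overlap`` additionally requires at
    least that many paired bases (None disables the check).  Each tag may
    participate in several duplexes; pairs are unique by their two
    alignments.
    """
    counts = {t.tag_id: t.counts for t in tags}
    minus_index: dict[tuple[str, int, int], list[TagAlignment]] = defaultdict(list)
    for a in alignments:
        if a.strand == "-":
            minus_index[(a.chrom, a.start, a.end)].append(a)

    duplexes: list[SiRNADuplex] = []
    seen: set[tuple] = set()
    for plus in alignments:
        if plus.strand != "+":
            continue
        for minus in minus_index.get((plus.chrom, plus.start - 2, plus.end - 2), []):
            key = (plus, minus)
            if key in seen:
                continue
            seen.add(key)
            overlap = minus.end - plus.start
            if min_overlap is not None and overlap < min_overlap:
                continue
            support = int(max(counts[plus.tag_id].max(), counts[minus.tag_id].max()))
            if support <= min_support:
                continue
            d = SiRNADuplex(
                duplex_id=f"dpx{len(duplexes) + 1:05d}",
                plus=plus,
                minus=minus,
            )
            d.support = support
            duplexes.append(d)
    duplexes.sort(key=lambda d: d.locus)
    for i, d in enumerate(duplexes):
        d.duplex_id = f"dpx{i + 1:05d}"
    return duplexes
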