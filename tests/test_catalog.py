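"""Tag collapsing, perfect-match mapping, class subtraction, duplex calling."""

import numpy as np
import pytest

from sirna_callus.catalog import (
    SRNATag,
    TagAlignment,
    call_duplexes,
    collapse_and_filter_reads,
    map_tags,
    revcomp,
    subtract_annotated_classes,
)


def brute_force_duplexes(alignments, tags, min_support=5, min_overlap=15):
    """Quadratic all-pairs reference for the duplex caller."""
    counts = {t.tag_id: t.counts for t in tags}
    pairs = set()
    for plus in alignments:
        if plus.strand != "+":
            continue
        for minus in alignments:
            if minus.strand != "-" or minus.chrom != plus.chrom:
                continue
            if plus.start - minus.start != 2 or plus.end - minus.end != 2:
                continue
            if min_overlap is not None and minus.end - plus.start < min_overlap:
                continue
            support = max(counts[plus.tag_id].max(), counts[minus.tag_id].max())
            if support > min_support:
                pairs.add((plus, minus))
    return pairs


def _mk_tag(tag_id, seq, counts=(9, 0, 0, 0)):
    return SRNATag(tag_id, seq, np.array(counts, dtype=int))


class TestCollapse:
    def test_identical_reads_collapse_with_per_library_counts(self):
        seq = "ACGTACGTACGTACGTACGT"
        tags = collapse_and_filter_reads({"CK": [seq] * 3, "I": [seq]})
        assert len(tags) == 1
        assert tags[0].counts.tolist() == [3, 1, 0, 0]

    def test_short_reads_removed(self):
        tags = collapse_and_filter_reads({"CK": ["ACGTACGTACGTACGT"]})  # 16 nt
        assert tags == []

    def test_u_mapped_to_t_and_bad_records_rejected(self):
        tags = collapse_and_filter_reads(
            {"CK": ["ACGUACGUACGUACGUACGU", "ACGTNNGTACGTACGTACGT"]}
        )
        assert len(tags) == 1
        assert "U" not in tags[0].sequence and "T" in tags[0].sequence

    def test_empty_input(self):
        assert collapse_and_filter_reads({}) == []


class TestMapping:
    genome = {"chr1": "".join(np.array(list("ACGT"))[np.random.default_rng(5).integers(0, 4, 400)])}

    def test_plus_strand_exact_hit(self):
        tag = _mk_tag("t1", self.genome["chr1"][100:121])
        _, alns = map_tags([tag], self.genome)
        assert alns == [TagAlignment("t1", "chr1", 100, 121, "+")]

    def test_minus_strand_exact_hit(self):
        tag = _mk_tag("t1", revcomp(self.genome["chr1"][98:119]))
        _, alns = map_tags([tag], self.genome)
        assert alns == [TagAlignment("t1", "chr1", 98, 119, "-")]

    def test_multi_hit_counted(self):
        word = "ACGTACGTACGTACGTACGTA"
        genome = {"chr1": "TT" + word + "CCCC" + word + "GG"}
        tag = _mk_tag("t1", word)
        tags, alns = map_tags([tag], genome)
        plus_hits = [a for a in alns if a.strand == "+"]
        assert len(plus_hits) == 2 and tags[0].hit_count == len(alns)

    def test_unmapped_tags_dropped(self):
        tags, alns = map_tags([_mk_tag("t1", "A" * 21)], self.genome)
        assert tags == [] and alns == []

    def test_alignments_reproduce_tag_sequence(self, bundle):
        """Perfect-match property on the synthetic study, every alignment."""
        from sirna_callus.catalog import tags_from_table

        tags = tags_from_table(
            bundle.tag_table[
                ["tag_id", "sequence", "count_CK", "count_I", "count_II", "count_III"]
            ].itertuples(index=False)
        )
        tags, alns = map_tags(tags, bundle.genome)
        seqs = {t.tag_id: t.sequence for t in tags}
        assert alns, "synthetic tags must map"
        for a in alns:
            sub = bundle.genome[a.chrom][a.start : a.end]
            expected = seqs[a.tag_id] if a.strand == "+" else revcomp(seqs[a.tag_id])
            assert sub == expected


class TestSubtraction:
    def _setup(self):
        tag = _mk_tag("t1", "ACGTACGTACGTACGTACGTA")
        aln = TagAlignment("t1", "chr1", 100, 121, "+")
        return [tag], [aln]

    def test_one_base_overlap_removes_tag(self):
        tags, alns = self._setup()
        kept_tags, kept_alns = subtract_annotated_classes(
            tags, alns, [("chr1", 120, 180, "rRNA")]
        )
        assert kept_tags == [] and kept_alns == []

    def test_no_overlap_retained(self):
        tags, alns = self._setup()
        kept_tags, _ = subtract_annotated_classes(tags, alns, [("chr1", 121, 180, "tRNA")])
        assert kept_tags == tags

    def test_empty_annotation_keeps_catalog(self):
        tags, alns = self._setup()
        assert subtract_annotated_classes(tags, alns, []) == (tags, alns)

    def test_unknown_class_rejected(self):
        tags, alns = self._setup()
        with pytest.raises(ValueError):
            subtract_annotated_classes(tags, alns, [("chr1", 0, 10, "lncRNA")])

    def test_subtraction_monotone(self):
        rng = np.random.default_rng(3)
        genome = {"chr1": "".join(np.array(list("ACGT"))[rng.integers(0, 4, 2000)])}
        tags = [_mk_tag(f"t{i}", genome["chr1"][s : s + 21]) for i, s in
                enumerate(range(0, 1900, 95))]
        tags, alns = map_tags(tags, genome)
        sizes = []
        intervals = []
        for extra in range(0, 2000, 400):
            intervals.append(("chr1", extra, extra + 50, "miRNA"))
            kept, _ = subtract_annotated_classes(tags, alns, list(intervals))
            sizes.append(len(kept))
        assert sizes == sorted(sizes, reverse=True)


class TestDuplexCalling:
    def _toy(self, minus_span=(98, 119), plus_span=(100, 121), counts=(7, 0, 0, 0)):
        rng = np.random.default_rng(9)
        genome = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
        plus_tag = _mk_tag("p", genome[plus_span[0] : plus_span[1]], counts)
        minus_tag = _mk_tag("m", revcomp(genome[minus_span[0] : minus_span[1]]), counts)
        alns = [
            TagAlignment("p", "chr1", *plus_span, "+"),
            TagAlignment("m", "chr1", *minus_span, "-"),
        ]
        return [plus_tag, minus_tag], alns

    def test_two_base_overhang_called(self):
        tags, alns = self._toy()
        duplexes = call_duplexes(alns, tags)
        assert len(duplexes) == 1
        assert duplexes[0].locus == ("chr1", 98, 121)
        assert duplexes[0].support == 7

    def test_support_threshold_is_strict(self):
        tags, alns = self._toy(counts=(5, 5, 5, 5))
        assert call_duplexes(alns, tags) == []
        tags, alns = self._toy(counts=(0, 6, 0, 0))
        assert len(call_duplexes(alns, tags)) == 1

    def test_three_base_overhang_rejected(self):
        tags, alns = self._toy(minus_span=(97, 118))
        assert call_duplexes(alns, tags) == []

    def test_short_overlap_rejected_by_default(self):
        tags, alns = self._toy(minus_span=(103, 119), plus_span=(105, 121))
        assert call_duplexes(alns, tags) == []
        assert len(call_duplexes(alns, tags, min_overlap=None)) == 1

    def test_matches_brute_force_on_random_catalog(self):
        rng = np.random.default_rng(17)
        genome = {"chr1": "".join(np.array(list("ACGT"))[rng.integers(0, 4, 5000)])}
        tags = []
        for i in range(30):  # single-stranded background tags
            s = int(rng.integers(0, 4970))
            L = int(rng.integers(18, 26))
            seq = genome["chr1"][s : s + L]
            if rng.random() < 0.5:
                seq = revcomp(seq)
            tags.append(_mk_tag(f"t{i}", seq, tuple(rng.integers(0, 20, 4))))
        for i in range(20):  # opposite-strand pairs at offsets 1..3 (only 2 is a duplex)
            s = int(rng.integers(0, 4900))
            L = int(rng.integers(18, 26))
            off = int(rng.integers(1, 4))
            tags.append(_mk_tag(f"m{i}", revcomp(genome["chr1"][s : s + L]),
                                tuple(rng.integers(0, 20, 4))))
            tags.append(_mk_tag(f"p{i}", genome["chr1"][s + off : s + off + L],
                                tuple(rng.integers(0, 20, 4))))
        tags, alns = map_tags(tags, genome)
        got = {(d.plus, d.minus) for d in call_duplexes(alns, tags)}
        assert got == brute_force_duplexes(alns, tags)
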