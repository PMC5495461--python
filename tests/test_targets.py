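"""Complementarity scoring, both association routes, degradome validation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from sirna_callus.catalog import revcomp
from sirna_callus.stats import DECall
from sirna_callus.targets import (
    CONCORDANT_PATTERNS,
    TargetSite,
    call_methyl_regions,
    cleavage_position,
    score_complementarity,
    select_cleavage_targets,
    select_methylation_targets,
    validate_cleavage_with_degradome,
)

RNG = np.random.default_rng(23)
TRANSCRIPT = "".join(np.array(list("ACGT"))[RNG.integers(0, 4, 200)])


def _de(feature, stage, direction, lfc=2.0):
    return DECall(feature_id=feature, comparison=f"{stage}_vs_CK", x=10, y=40,
                  N1=1e6, N2=1e6, rpm_ck=10, rpm_stage=40,
                  log2fc=lfc if direction == "up" else -lfc,
                  p=1e-4, q=1e-3, direction=direction)


class TestScoring:
    def test_perfect_complement_scores_zero(self):
        w = 50
        sirna = revcomp(TRANSCRIPT[w : w + 21])
        sites = score_complementarity(sirna, TRANSCRIPT, max_penalty=0.0)
        assert (w, w + 21, 0.0) in sites

    def test_gu_wobble_in_core_costs_one(self):
        w, L = 50, 21
        window = list(TRANSCRIPT[w : w + L])
        sirna = list(revcomp("".join(window)))
        # guide position 5 faces transcript index w + L - 5; make it G:U
        sirna[4] = "G"
        window[L - 5] = "T"
        transcript = TRANSCRIPT[:w] + "".join(window) + TRANSCRIPT[w + L :]
        sites = dict(
            ((s, e), p) for s, e, p in score_complementarity("".join(sirna), transcript)
        )
        assert sites[(w, w + L)] == pytest.approx(1.0)

    def test_five_core_mismatches_cost_ten_and_are_cut(self):
        w, L = 50, 21
        window = list(TRANSCRIPT[w : w + L])
        sirna = list(revcomp("".join(window)))
        flip = {"A": "C", "C": "A", "G": "T", "T": "G"}  # mismatch, never wobble
        for pos in (3, 5, 7, 9, 11):  # guide positions 4,6,8,10,12 (0-based idx)
            sirna[pos] = flip[sirna[pos]]
        hits = score_complementarity("".join(sirna), TRANSCRIPT, max_penalty=20.0)
        penalties = {(s, e): p for s, e, p in hits}
        assert penalties[(w, w + L)] == pytest.approx(10.0)
        assert (w, w + L) not in {
            (s, e) for s, e, _ in score_complementarity("".join(sirna), TRANSCRIPT)
        }

    def test_sirna_longer_than_transcript(self):
        assert score_complementarity("A" * 30, "ACGT" * 5) == []

    def test_zero_penalty_equals_brute_force_search(self):
        rng = np.random.default_rng(31)
        transcript = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 500)])
        for _ in range(20):
            w = int(rng.integers(0, 475))
            L = int(rng.integers(20, 25))
            sirna = revcomp(transcript[w : w + L])
            got = {s for s, _, p in score_complementarity(sirna, transcript, 0.0)}
            rc = revcomp(sirna)
            expected = {
                i for i in range(len(transcript) - L + 1) if transcript[i : i + L] == rc
            }
            assert got == expected

    def test_raising_cutoff_never_removes_sites(self):
        sirna = revcomp(TRANSCRIPT[30:52])
        prev: set = set()
        for cutoff in (0.0, 1.0, 2.0, 4.0, 8.0):
            cur = {(s, e) for s, e, _ in score_complementarity(sirna, TRANSCRIPT, cutoff)}
            assert prev <= cur
            prev = cur


class TestCleavageSelection:
    def _fixture(self):
        sirna_de = [_de("s1", "I", "up")]
        gene_de = [_de("g1", "I", "down")]
        sites = [TargetSite("s1", "g1", "sense", (10, 31), "CDS", 0.0)]
        sirna_rpm = {"s1": np.array([10.0, 40.0, 40.0, 40.0])}
        gene_rpm = {"g1": np.array([40.0, 10.0, 10.0, 10.0])}
        lengths = {"s1": 21}
        return sirna_de, sites, gene_de, sirna_rpm, gene_rpm, lengths

    def test_planted_link_retained(self):
        out = select_cleavage_targets(*self._fixture())
        assert len(out) == 1
        it = out[0]
        assert it.mode == "cleavage" and it.corr_sirna_gene < -0.4
        assert it.stages_supported == ("I",)

    def test_24nt_sense_site_excludes_gene(self):
        sirna_de, sites, gene_de, sirna_rpm, gene_rpm, lengths = self._fixture()
        sirna_de.append(_de("s24", "I", "up"))
        sites.append(TargetSite("s24", "g1", "sense", (60, 84), "CDS", 0.0))
        sirna_rpm["s24"] = np.array([10.0, 40.0, 40.0, 40.0])
        lengths["s24"] = 24
        assert select_cleavage_targets(sirna_de, sites, gene_de, sirna_rpm, gene_rpm,
                                       lengths) == []

    def test_non_de_24nt_ignored_by_default_but_not_in_all_mode(self):
        sirna_de, sites, gene_de, sirna_rpm, gene_rpm, lengths = self._fixture()
        sites.append(TargetSite("quiet24", "g1", "sense", (60, 84), "CDS", 0.0))
        sirna_rpm["quiet24"] = np.array([10.0, 10.0, 10.0, 10.0])
        lengths["quiet24"] = 24
        assert len(select_cleavage_targets(sirna_de, sites, gene_de, sirna_rpm,
                                           gene_rpm, lengths)) == 1
        assert select_cleavage_targets(sirna_de, sites, gene_de, sirna_rpm, gene_rpm,
                                       lengths, exclude_24nt="all") == []

    def test_weak_anticorrelation_excluded(self):
        sirna_de, sites, gene_de, sirna_rpm, gene_rpm, lengths = self._fixture()
        gene_rpm["g1"] = np.array([40.0, 10.0, 45.0, 38.0])  # corr > -0.4
        from sirna_callus.stats import log_profile, profile_correlation

        corr = profile_correlation(log_profile(sirna_rpm["s1"]), log_profile(gene_rpm["g1"]))
        assert corr > -0.4
        assert select_cleavage_targets(sirna_de, sites, gene_de, sirna_rpm, gene_rpm,
                                       lengths) == []

    def test_antisense_site_not_enough(self):
        sirna_de, sites, gene_de, sirna_rpm, gene_rpm, lengths = self._fixture()
        sites[0].transcript_strand_targeted = "antisense"
        assert select_cleavage_targets(sirna_de, sites, gene_de, sirna_rpm, gene_rpm,
                                       lengths) == []

    def test_unknown_gene_rejected(self):
        sirna_de, sites, gene_de, sirna_rpm, gene_rpm, lengths = self._fixture()
        sites.append(TargetSite("s1", "ghost", "sense", (0, 21), "CDS", 0.0))
        with pytest.raises(ValueError, match="unknown gene"):
            select_cleavage_targets(sirna_de, sites, gene_de, sirna_rpm, gene_rpm, lengths)

    def test_tightening_correlation_never_adds(self):
        args = self._fixture()
        loose = select_cleavage_targets(*args, corr_thresh=-0.2)
        tight = select_cleavage_targets(*args, corr_thresh=-0.9)
        assert {(i.sirna_id, i.gene_id) for i in tight} <= {
            (i.sirna_id, i.gene_id) for i in loose
        }


class TestMethylRegions:
    totals = [1e6] * 4

    def _signal(self, counts):
        return pd.DataFrame(
            [dict(region_id="r1", count_CK=counts[0], count_I=counts[1],
                  count_II=counts[2], count_III=counts[3])]
            + [
                dict(region_id=f"bg{i}", count_CK=50, count_I=50, count_II=50,
                     count_III=50)
                for i in range(20)
            ]
        )

    def _regions(self):
        rows = [dict(chrom="chr1", start=0, end=50, name="r1", score=0, strand=".",
                     gene_id="g1", role="3'UTR")]
        return pd.DataFrame(rows)

    def test_strong_hyper_called(self):
        calls = call_methyl_regions(self._signal([50, 200, 210, 190]), self._regions(),
                                    self.totals)
        r1 = next(c for c in calls if c.region_id == "r1")
        assert all(r1.direction[s] == "hyper" for s in ("I", "II", "III"))

    def test_ratio_below_two_is_ns(self):
        calls = call_methyl_regions(self._signal([5000, 9000, 9000, 9000]),
                                    self._regions(), self.totals)
        r1 = next(c for c in calls if c.region_id == "r1")
        assert all(v == "ns" for v in r1.direction.values())
        assert all(q < 0.05 for q in r1.q.values())  # blocked by the ratio alone

    def test_low_signal_is_ns(self):
        # 0.1 RPM everywhere: below the 0.25-RPM mean-signal screen
        signal = pd.DataFrame(
            [dict(region_id="r1", count_CK=0, count_I=0, count_II=0, count_III=0)]
        )
        calls = call_methyl_regions(signal, self._regions(), self.totals)
        assert all(v == "ns" for v in calls[0].direction.values())

    def test_hypo_direction(self):
        calls = call_methyl_regions(self._signal([200, 40, 45, 50]), self._regions(),
                                    self.totals)
        r1 = next(c for c in calls if c.region_id == "r1")
        assert r1.direction["I"] == "hypo"


class TestMethylationSelection:
    def _scenario(self, sirna_dir, methyl_dir, gene_dir, length=24):
        """One stage, one candidate pair, fully controllable signs."""
        from sirna_callus.targets import MethylRegionCall

        sirna_de = [_de("s1", "I", sirna_dir)] if sirna_dir else []
        gene_de = [_de("g1", "I", gene_dir)] if gene_dir else []
        sites = [TargetSite("s1", "g1", "antisense", (140, 164), "3'UTR", 0.0)]
        call = MethylRegionCall("r1", "g1", "3'UTR",
                                rpm=np.array([50.0, 200.0, 50.0, 50.0])
                                if methyl_dir == "hyper"
                                else np.array([200.0, 50.0, 200.0, 200.0]))
        for s in ("I", "II", "III"):
            call.q[s] = 1e-4
            call.ratio[s] = 4.0
            call.direction[s] = methyl_dir if s == "I" else "ns"
        up = np.array([10.0, 40.0, 10.0, 10.0])
        down = np.array([40.0, 10.0, 40.0, 40.0])
        sirna_rpm = {"s1": up if sirna_dir == "up" else down}
        gene_rpm = {"g1": up if gene_dir == "up" else down}
        methyl_rpm = {"g1": up if methyl_dir == "hyper" else down}
        lengths = {"s1": length}
        return (sirna_de, sites, [call], gene_de, sirna_rpm, gene_rpm, methyl_rpm,
                lengths)

    def test_concordance_truth_table(self):
        """Exactly the two concordant sign patterns yield interactions."""
        for s_dir, m_dir, g_dir in itertools.product(
            ["up", "down"], ["hyper", "hypo"], ["up", "down"]
        ):
            out = select_methylation_targets(*self._scenario(s_dir, m_dir, g_dir))
            expected = (s_dir, m_dir, g_dir) in CONCORDANT_PATTERNS
            assert bool(out) == expected, (s_dir, m_dir, g_dir)
            if out:
                assert out[0].methyl_direction == m_dir
                assert out[0].corr_sirna_gene < -0.4
                assert out[0].corr_methyl_gene < -0.4

    def test_non_24nt_ineligible(self):
        out = select_methylation_targets(*self._scenario("up", "hyper", "down",
                                                         length=22))
        assert out == []


class TestDegradome:
    site = TargetSite("s1", "g1", "sense", (18, 42), "5'UTR", 0.0)

    def _cov(self, peak_at, peak_count=60):
        rows = [dict(transcript_id="g1", position=p, count=2) for p in range(5, 100, 7)]
        rows.append(dict(transcript_id="g1", position=peak_at, count=peak_count))
        return pd.DataFrame(rows)

    def test_predicted_position_convention(self):
        # 24-nt guide on a window starting at transcript position 18 slices
        # so that the downstream fragment starts opposite guide base 10
        assert cleavage_position(18, 24) == 32

    def test_peak_at_predicted_position_confirms(self):
        v = validate_cleavage_with_degradome(self.site, self._cov(32))
        assert v.confirmed and v.peak_pos == 32

    def test_displaced_peak_unconfirmed(self):
        v = validate_cleavage_with_degradome(self.site, self._cov(37))
        assert not v.confirmed

    def test_flat_coverage_unconfirmed(self):
        for step in (5, 4):  # the second grid covers the predicted position itself
            flat = pd.DataFrame(
                [dict(transcript_id="g1", position=p, count=3) for p in range(0, 100, step)]
            )
            v = validate_cleavage_with_degradome(self.site, flat)
            assert not v.confirmed

    def test_no_coverage_unconfirmed(self):
        v = validate_cleavage_with_degradome(self.site, pd.DataFrame(
            columns=["transcript_id", "position", "count"]))
        assert not v.confirmed and v.peak_pos is None
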