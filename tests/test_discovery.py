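"""Novel-miRNA discovery tests: genome mapping, precursor excision, the
criteria checklist, family clustering and genomic-context annotation."""

import pytest

from mirforge._seq import revcomp
from mirforge.discovery import (
    GenomeLocus,
    MiRNACall,
    annotate_genomic_context,
    cluster_families,
    excise_precursors,
    map_tags_to_genome,
    parse_gff3,
)
from mirforge.preprocess import UniqueTag

import helpers


def _tags(*seqs, count=20):
    return {s: UniqueTag(seq=s, counts={"s": count}) for s in seqs}


class TestMapping:
    GENOME = {"chr1": "A" * 10 + "TGGACGTGATCGTAGCAGTTC" + "G" * 30}

    def test_forward_placement(self):
        tag = "TGGACGTGATCGTAGCAGTTC"
        placements, multi = map_tags_to_genome(_tags(tag), self.GENOME)
        assert placements[tag] == [GenomeLocus("chr1", 10, 31, "+")]
        assert not multi

    def test_minus_strand_placement(self):
        tag = revcomp("TGGACGTGATCGTAGCAGTTC")
        placements, _ = map_tags_to_genome(_tags(tag), self.GENOME)
        assert placements[tag] == [GenomeLocus("chr1", 10, 31, "-")]

    def test_multimapped_excluded(self):
        genome = {"chr1": ("TGGACGTGATCGTAGCAGTTC" + "AAAA") * 20}
        tag = "TGGACGTGATCGTAGCAGTTC"
        placements, multi = map_tags_to_genome(_tags(tag), genome, max_loci=15)
        assert tag in multi and tag not in placements

    def test_agrees_with_naive_scan(self, rng):
        genome = {"chr1": "".join(rng.choice(list("ACGT"), size=5000))}
        text = genome["chr1"]
        for _ in range(25):
            p = int(rng.integers(0, 4979))
            tag = text[p : p + 21]
            if rng.random() < 0.5:
                tag = revcomp(tag)
            placements, _ = map_tags_to_genome(_tags(tag), genome)
            expected = []
            for i in range(len(text) - 20):
                if text[i : i + 21] == tag:
                    expected.append(GenomeLocus("chr1", i, i + 21, "+"))
            for i in range(len(text) - 20):
                if text[i : i + 21] == revcomp(tag):
                    expected.append(GenomeLocus("chr1", i, i + 21, "-"))
            assert placements.get(tag, []) == expected


class TestExcision:
    GENOME = {"chr1": "".join("ACGT"[i % 4] for i in range(10_000))}

    def test_window_arithmetic(self):
        locus = GenomeLocus("chr1", 1000, 1021, "+")
        seeds = excise_precursors(locus, self.GENOME)
        spans = {(s.locus.start, s.locus.end) for s in seeds}
        assert spans == {(980, 1230), (791, 1041)}
        for s in seeds:
            assert s.seq[s.mature_offset : s.mature_offset + 21] == (
                self.GENOME["chr1"][1000:1021]
            )

    def test_clipped_at_chromosome_start(self):
        locus = GenomeLocus("chr1", 5, 26, "+")
        seeds = excise_precursors(locus, self.GENOME)
        assert all(s.locus.start >= 0 for s in seeds)
        assert any(s.locus.start == 0 for s in seeds)

    def test_minus_strand_revcomp(self):
        locus = GenomeLocus("chr1", 1000, 1021, "-")
        for s in excise_precursors(locus, self.GENOME):
            raw = self.GENOME["chr1"][s.locus.start : s.locus.end]
            assert s.seq == revcomp(raw)
            assert s.seq[s.mature_offset : s.mature_offset + 21] == revcomp(
                self.GENOME["chr1"][1000:1021]
            )


class TestCriteriaChecklist:
    def test_compliant_hairpin_accepted(self):
        c = helpers.evaluate_control(helpers.compliant_precursor(), counts=50)
        assert c.accepted
        assert all(v is True for v in c.verdicts.values())
        assert c.duplex_pairs == 19  # full stem minus the 2-nt overhangs
        assert c.len_diff == 0
        assert c.shuffle_p is not None and c.shuffle_p <= 0.05
        assert c.mfe is not None and c.mfe < -20.0

    def test_short_duplex_rejected_with_duplex_key(self):
        c = helpers.evaluate_control(helpers.duplex13_precursor())
        assert not c.accepted
        assert c.duplex_pairs == 13
        assert c.verdicts["duplex14"] is False
        assert "duplex14" in c.rejection_reasons

    def test_nine_reads_rejected_ten_accepted(self):
        c9 = helpers.evaluate_control(helpers.compliant_precursor(), counts=9)
        assert not c9.accepted and c9.rejection_reasons == ["min_reads"]
        c10 = helpers.evaluate_control(helpers.compliant_precursor(), counts=10)
        assert c10.accepted

    def test_length_delta7_rejected_with_len_key(self):
        c = helpers.evaluate_control(helpers.len_delta7_precursor())
        assert not c.accepted
        assert c.len_diff == 7
        assert c.verdicts["len_diff6"] is False
        assert c.verdicts["duplex14"] is True  # the duplex itself is intact

    def test_bifurcated_rejected_with_bifurcation_key(self):
        c = helpers.evaluate_control(helpers.bifurcated_precursor())
        assert not c.accepted
        assert c.rejection_reasons == ["no_bifurcation"]

    def test_unfolded_seed_rejected(self):
        from mirforge.discovery import PrecursorCandidate, evaluate_candidate

        seed = PrecursorCandidate(
            locus=GenomeLocus("c", 0, 30, "+"),
            seq="ACGT" * 10,
            mature_seq="ACGT" * 5,
            mature_offset=0,
        )
        with pytest.raises(ValueError):
            evaluate_candidate(seed, [])

    def test_star_read_evidence_flag_not_a_gate(self):
        from mirforge.discovery import (
            LocusTag,
            PrecursorCandidate,
            evaluate_candidate,
            fold_candidate,
        )
        from mirforge.preprocess import UniqueTag
        from mirforge.synthetic import build_hairpin_precursor

        pre, star = build_hairpin_precursor(helpers.MATURE, "5p", 8, 0.0, 1)
        no_star = helpers.evaluate_control(pre, counts=50)
        assert no_star.accepted and not no_star.star_evidence

        cand = PrecursorCandidate(
            locus=GenomeLocus("ctrl", 1000, 1000 + len(pre), "+"),
            seq=pre,
            mature_seq=helpers.MATURE,
            mature_offset=0,
        )
        fold_candidate(cand, "energy")
        tags = [
            LocusTag(UniqueTag(helpers.MATURE, {"shoot": 50}), 0),
            LocusTag(UniqueTag(star, {"shoot": 5}), pre.find(star)),
        ]
        evaluate_candidate(cand, tags)
        assert cand.star_evidence and cand.accepted


def _call(cid, seq, class_="novel", family="unassigned", total=10, loci=None):
    return MiRNACall(
        id=cid,
        seq=seq,
        class_=class_,
        family=family,
        loci=loci or [],
        counts={"s": total},
    )


class TestFamilies:
    def test_identical_sequences_one_family(self):
        calls = [_call("a", "TGACAGAAGAGAGTGAGCACA"), _call("b", "TGACAGAAGAGAGTGAGCACA")]
        fams = cluster_families(calls)
        assert len(fams) == 1 and set(fams[0].members) == {"a", "b"}

    def test_distant_sequences_split(self):
        a = "TGACAGAAGAGAGTGAGCACA"
        b = list(a)
        for i in (2, 6, 10, 14, 18):
            b[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[b[i]]
        calls = [_call("a", a), _call("b", "".join(b))]
        fams = cluster_families(calls)  # identity 16/21 = 0.762 < 0.90
        assert len(fams) == 2

    def test_novel_near_conserved_becomes_isoform(self):
        a = "TGACAGAAGAGAGTGAGCACA"
        b = a[:-1] + ("G" if a[-1] != "G" else "T")
        calls = [
            _call("cons", a, class_="conserved", family="miR156", total=100),
            _call("nov", b, class_="novel", total=10),
        ]
        fams = cluster_families(calls)
        assert len(fams) == 1 and fams[0].family_id == "miR156"
        nov = [c for c in calls if c.id == "nov"][0]
        assert nov.class_ == "novel_isoform" and nov.family == "miR156"

    def test_deterministic_given_sort_order(self):
        calls1 = [_call(f"c{i}", "TGACAGAAGAGAGTGAGCACA") for i in range(4)]
        calls2 = list(reversed([_call(f"c{i}", "TGACAGAAGAGAGTGAGCACA") for i in range(4)]))
        f1 = cluster_families(calls1)
        f2 = cluster_families(calls2)
        assert [sorted(f.members) for f in f1] == [sorted(f.members) for f in f2]

    def test_consensus_majority(self):
        calls = [
            _call("a", "TGACAGAAGAGAGTGAGCACA", total=30),
            _call("b", "TGACAGAAGAGAGTGAGCACA", total=20),
            _call("c", "AGACAGAAGAGAGTGAGCACA", total=10),
        ]
        fams = cluster_families(calls)
        assert fams[0].consensus == "TGACAGAAGAGAGTGAGCACA"


GFF = """##gff-version 3
chr1\tsrc\tgene\t1001\t5000\t.\t+\t.\tID=g1
chr1\tsrc\tmRNA\t1001\t5000\t.\t+\t.\tID=m1;Parent=g1
chr1\tsrc\tfive_prime_UTR\t1001\t1100\t.\t+\t.\tParent=m1
chr1\tsrc\tCDS\t1101\t2000\t.\t+\t.\tParent=m1
chr1\tsrc\tCDS\t3001\t4000\t.\t+\t.\tParent=m1
"""


class TestGenomicContext:
    def _annotate(self, loci, families=None, path=None, window=10_000):
        calls = [
            _call(f"c{i}", "TGACAGAAGAGAGTGAGCACA", family=(families or {}).get(i, "f"), loci=[loc])
            for i, loc in enumerate(loci)
        ]
        return annotate_genomic_context(calls, path, cluster_window=window), calls

    @pytest.fixture()
    def gff(self, tmp_path):
        p = tmp_path / "ann.gff3"
        p.write_text(GFF)
        return str(p)

    def test_intron_classification(self, gff):
        (ctx, _), _ = self._annotate([GenomeLocus("chr1", 2500, 2521, "+")], path=gff)
        assert ctx["c0"] == "intron"

    def test_cds_precedence(self, gff):
        # spans the CDS/intron boundary: CDS wins
        (ctx, _), _ = self._annotate([GenomeLocus("chr1", 1990, 2011, "+")], path=gff)
        assert ctx["c0"] == "CDS"

    def test_utr_and_intergenic(self, gff):
        (ctx, _), _ = self._annotate(
            [GenomeLocus("chr1", 1010, 1031, "+"), GenomeLocus("chr1", 8000, 8021, "+")],
            path=gff,
        )
        assert ctx["c0"] == "UTR" and ctx["c1"] == "intergenic"

    def test_tandem_cluster_window(self, gff):
        (_, clusters), _ = self._annotate(
            [
                GenomeLocus("chr1", 1000, 1021, "+"),
                GenomeLocus("chr1", 6000, 6021, "+"),
                GenomeLocus("chr1", 30_000, 30_021, "+"),
            ],
            path=gff,
        )
        assert len(clusters) == 1
        assert clusters[0]["members"] == ["c0", "c1"]
        assert clusters[0]["kind"] == "same_family"

    def test_mixed_family_cluster(self, gff):
        (_, clusters), _ = self._annotate(
            [GenomeLocus("chr1", 1000, 1021, "+"), GenomeLocus("chr1", 2000, 2021, "+")],
            families={0: "miR156", 1: "miR172"},
            path=gff,
        )
        assert clusters[0]["kind"] == "mixed"

    def test_malformed_gff_reports_line(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text("##gff-version 3\nchr1\tonly\tthree\n")
        with pytest.raises(ValueError, match="line 2"):
            parse_gff3(str(p))
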