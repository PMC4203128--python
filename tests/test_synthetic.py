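"""Generator tests: hairpin construction, genome planting, read simulation."""

import pytest
from Bio import SeqIO

from mirforge._seq import revcomp
from mirforge.structure import fold_energy, fold_maxpair, parse_hairpin
from mirforge.synthetic import (
    SyntheticConfig,
    build_hairpin_precursor,
    plant_genome,
    simulate_read_libraries,
    write_genome_fasta,
)

MATURE = "TGGACGTGATCGTAGCAGTTC"  # 21 nt


class TestHairpin:
    @pytest.mark.parametrize("arm", ["5p", "3p"])
    def test_perfect_stem_pairs_full_mature(self, arm):
        pre, star = build_hairpin_precursor(MATURE, arm=arm, loop_len=8, rng_seed=1)
        f = fold_maxpair(pre)
        assert f.score == len(MATURE)  # every mature base paired in the stem
        assert len(star) == len(MATURE)
        # the energy fold resolves the co-optimal tangle into one hairpin
        anat = parse_hairpin(fold_energy(pre))
        assert anat.n_hairpin_loops == 1 and not anat.has_bifurcation

    def test_star_geometry_5p(self):
        pre, star = build_hairpin_precursor(MATURE, arm="5p", loop_len=8, rng_seed=1)
        # star = revcomp of mature minus the 2 overhang positions + 2-nt ext
        assert star[:-2] == revcomp(MATURE)[2:]
        assert pre.startswith(MATURE) and pre.endswith(star[-2:])

    def test_star_geometry_3p(self):
        pre, star = build_hairpin_precursor(MATURE, arm="3p", loop_len=8, rng_seed=1)
        assert star[:-2] == revcomp(MATURE)[2:]
        assert pre.endswith(MATURE)

    def test_deterministic(self):
        a = build_hairpin_precursor("ACGT" * 5 + "A", rng_seed=42)
        b = build_hairpin_precursor("ACGT" * 5 + "A", rng_seed=42)
        assert a == b

    def test_loop_too_short_rejected(self):
        with pytest.raises(ValueError):
            build_hairpin_precursor(MATURE, loop_len=2)

    @pytest.mark.parametrize("mature", ["ACGTACGTACGTACGTACG"[:19], "A" * 25])
    def test_bad_mature_length_rejected(self, mature):
        with pytest.raises(ValueError):
            build_hairpin_precursor(mature)

    def test_mutations_capped(self):
        pre, star = build_hairpin_precursor(
            MATURE, loop_len=8, mutation_rate=0.5, rng_seed=3
        )
        # even at high mutation rate, >= 80% of stem pairs survive
        f = fold_energy(pre)
        assert f.score < -15


class TestPlantGenome:
    def test_zero_loci(self):
        cfg = SyntheticConfig(n_loci=0, genome_length=5000)
        genome, truth = plant_genome(cfg)
        assert truth.records == [] and len(genome["chr1"]) == 5000

    def test_self_consistency(self):
        cfg = SyntheticConfig(n_loci=10, genome_length=100_000, seed=5)
        genome, truth = plant_genome(cfg)
        for rec in truth.records:
            loc = rec.locus
            sl = genome[loc.chrom][loc.start : loc.end]
            expect = rec.precursor_seq if loc.strand == "+" else revcomp(
                rec.precursor_seq
            )
            assert sl == expect
            ml = rec.mature_locus
            got = genome[ml.chrom][ml.start : ml.end]
            assert got == (rec.mature_seq if ml.strand == "+" else revcomp(rec.mature_seq))

    def test_loci_do_not_overlap(self):
        cfg = SyntheticConfig(n_loci=20, genome_length=100_000, seed=2)
        _genome, truth = plant_genome(cfg)
        spans = sorted((r.locus.start, r.locus.end) for r in truth.records)
        for (s1, e1), (s2, _e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_byte_identical_fasta_under_fixed_seed(self, tmp_path):
        cfg = SyntheticConfig(n_loci=5, genome_length=20_000, seed=9)
        for name in ("a.fa", "b.fa"):
            genome, _ = plant_genome(cfg)
            write_genome_fasta(genome, tmp_path / name)
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()

    def test_impossible_placement_reports_fit(self):
        with pytest.raises(ValueError):
            # invariant check rejects before placement is even attempted
            SyntheticConfig(n_loci=100, genome_length=5_000)

    def test_background_composition_uniform(self):
        cfg = SyntheticConfig(n_loci=0, genome_length=40_000, seed=3)
        genome, _ = plant_genome(cfg)
        seq = genome["chr1"]
        n = len(seq)
        for b in "ACGT":
            # binomial(n, 1/4): 5 sigma band
            sd = (n * 0.25 * 0.75) ** 0.5
            assert abs(seq.count(b) - n * 0.25) < 5 * sd


class TestSimulateReads:
    def _small_truth(self, counts, star_fraction=0.1, **kw):
        cfg = SyntheticConfig(
            n_loci=1,
            genome_length=5000,
            tissues=("shoot",),
            star_fraction=star_fraction,
            seed=4,
            count_profiles=(counts,),
            **kw,
        )
        genome, truth = plant_genome(cfg)
        return cfg, truth

    def test_exact_insert_counts(self, tmp_path):
        cfg, truth = self._small_truth({"shoot": 50})
        paths = simulate_read_libraries(truth, cfg, tmp_path)
        rec = truth.records[0]
        reads = [str(r.seq) for r in SeqIO.parse(str(paths["shoot"]), "fastq")]
        mature = sum(r.startswith(rec.mature_seq + cfg.adapter_seq[:5]) for r in reads)
        star = sum(r.startswith(rec.star_seq + cfg.adapter_seq[:5]) for r in reads)
        assert mature == 50 and star == 5
        assert len(reads) == 55

    def test_all_records_parse_as_fastq_phred33(self, tmp_path):
        cfg, truth = self._small_truth({"shoot": 20})
        paths = simulate_read_libraries(truth, cfg, tmp_path)
        for r in SeqIO.parse(str(paths["shoot"]), "fastq"):
            quals = r.letter_annotations["phred_quality"]
            assert len(quals) == len(r.seq) == cfg.read_length
            assert all(q >= 0 for q in quals)

    def test_zero_noise_inserts_match_truth(self, tmp_path):
        cfg, truth = self._small_truth({"shoot": 30})
        paths = simulate_read_libraries(truth, cfg, tmp_path)
        rec = truth.records[0]
        allowed = {rec.mature_seq, rec.star_seq}
        for r in SeqIO.parse(str(paths["shoot"]), "fastq"):
            s = str(r.seq)
            assert any(s.startswith(a) for a in allowed)

    def test_jitter_run_is_reproducible(self, tmp_path):
        cfg, truth = self._small_truth({"shoot": 40}, end_jitter_prob=0.2)
        p1 = simulate_read_libraries(truth, cfg, tmp_path / "r1")
        p2 = simulate_read_libraries(truth, cfg, tmp_path / "r2")
        assert p1["shoot"].read_bytes() == p2["shoot"].read_bytes()

    def test_unknown_tissue_rejected(self, tmp_path):
        cfg, truth = self._small_truth({"shoot": 10})
        truth.records[0].per_tissue_count = {"petal": 5}
        with pytest.raises(ValueError):
            simulate_read_libraries(truth, cfg, tmp_path)

    def test_empty_simulation_rejected(self, tmp_path):
        cfg = SyntheticConfig(n_loci=0, genome_length=5000)
        _genome, truth = plant_genome(cfg)
        with pytest.raises(ValueError):
            simulate_read_libraries(truth, cfg, tmp_path)
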