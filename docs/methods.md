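# Methods

This note documents the models, parameters and design choices behind
`mirforge`, in the package's own terms. Nothing here states an empirical
result that the tests or `scripts/acceptance.py` do not themselves
compute.

## The synthetic study

The generator (`mirforge.synthetic`) is the package's study design: it
defines the conditions under which every claim about the pipeline is
tested.

**Genome.** One chromosome of i.i.d. uniform ACGT background (default
100 kb) carrying `n_loci = 20` non-overlapping planted hairpins, each
with ≥ 30 bp random flank, on random strands.

**Hairpins.** A mature sequence (20–24 nt, cycling through lengths
21/21/21/24/22/20 to emulate the 21-nt-dominated size profile of plant
miRNAs, with a 60 % 5′-U bias) is embedded as

    5p arm:  mature + loop + revcomp(mature) + 2 nt
    3p arm:  revcomp(mature) + loop + mature

The full mature is paired in the stem; the mature:star duplex obeys the
2-nt 3′-overhang rule, with the overhanging mature bases pairing stem
bases just outside the star span, as in genuine pre-miRNAs. The star is
therefore `revcomp(mature)[2:]` plus the two bases past the partner of
the mature 5′ end, and the mature:star duplex of an L-nt mature has
exactly L−2 paired positions (19 for a 21-mer) — comfortably above the
14-bp acceptance floor. Loop (8 nt) and extension bases are drawn from
{A, C} only, so they cannot pair with each other and a zero-mutation
precursor has no competing structure *within the loop*. Stem
imperfections (`mutation_rate`) convert up to 20 % of stem pairs into
G:U wobbles or mismatches on the non-mature arm.

**Reads.** Per-tissue mature counts are explicit integers (deterministic
profiles cycling uniform / single-tissue / graded across loci: 50 per
tissue, 120 in one tissue, or 20·rank), so truth is exact; a lognormal
mode exists for stress tests but is deliberately uncalibrated. Star reads
appear at `star_fraction = 0.1` of the mature count, every read carries
the 3′ TruSeq small-RNA adapter and constant Q30 qualities (Phred+33),
and optional knobs inject ±1-nt end jitter, low-quality reads, and
rRNA/tRNA-like contaminant substrings. With all noise knobs at 0 the
multiset of inserts equals the truth counts exactly.

**What the generator does not emulate** — sequencing error, ligation
bias, repeats, isomiR ladders, genome assembly artifacts. Passing tests
therefore demonstrate the correctness of the pipeline's logic under its
stated rules, not its robustness to real library chemistry.

## Folding

`structure.fold_maxpair` is a Nussinov dynamic program maximizing nested
canonical pairs (AU/GC/GU) with a ≥ 3-nt hairpin loop; traceback is
deterministic (pair *i* with the smallest qualifying partner). It is
exact — verified against brute-force enumeration of all nested
structures for n ≤ 12.

`structure.fold_energy` is a reduced Zuker recursion over a
nearest-neighbor table shipped as editable TSV
(`mirforge/data/energy_params.tsv`): Turner-like Watson–Crick stack free
energies, a uniform −0.5 kcal/mol for wobble-containing stacks, hairpin
and internal/bulge penalties by loop length with logarithmic
extrapolation, and a linear multiloop cost (a = 3.4, b = 0.4 per branch,
c = 0 per unpaired base). Internal loops are capped at 30 unpaired
bases. The open chain is the 0 kcal/mol reference. Absolute energies
approximate, rather than reproduce, a full thermodynamic folder; −20
kcal/mol is used only as a reporting statistic, never a filter. The
table is rotation-symmetric, so a perfect stem and its reverse
complement fold to identical energies.

**Which fold drives the criteria.** The structural verdicts and the
shuffle test run on the *energy* fold (`DiscoveryThresholds.fold_mode`,
maxpair selectable). Maximum-pairing folds of a 250-nt window are dense
co-optimal tangles: the planted stem need not appear in any traced
optimum, and dinucleotide-shuffled nulls reach nearly the same pair
count, which makes both the anatomy checks and the significance test
uninformative at window scale. The energy model, like the thermodynamic
folders used in practice, recovers the planted stem as the unique
optimum in all constructions tested. For the same reason the
single-hairpin anatomy guarantee for zero-mutation precursors holds on
the energy fold; the maxpair fold guarantees the pair *count* (= mature
length) but may trace a co-optimal bifurcated alternative.

## Shuffle significance

`shuffle_pvalue` is a RANDfold-style empirical test: the observed fold
score against `n_shuffles = 99` Altschul–Erickson dinucleotide-preserving
shuffles (random last-edge arborescence + randomized edge orderings,
walked as an Eulerian path), p = (1 + #{null at least as stable}) /
(n + 1). "At least as stable" is `≤` for free energies and `≥` for pair
counts. 99 shuffles is the smallest round count that resolves p ≤ 0.05
with margin; homopolymers give p = 1 exactly and p ≥ 1/(n+1) always.
Inside discovery the test is evaluated last and only when the seven
cheaper verdicts already pass; a skipped test is recorded as `None`,
never as a pass.

## Discovery

Tags map to the genome by exact full-length search on both strands;
tags with > 15 placements are set aside as multi-mapped. Around each
placement two 250-bp windows are excised (tag 20 bp from either window
edge, clipped at chromosome bounds, minus-strand windows
reverse-complemented). The star is inferred from the fold by the
overhang rule — star span = [partner(mature₃′₋₂), partner(mature₅′) + 2]
— with linear extrapolation across unpaired mature positions. Dicer
consistency is the read-count fraction at the locus sharing the mature
5′ start (threshold 0.5, the cited criterion being named but
unquantified). Star-read presence is a confidence flag, not a gate.

A perfect-stem hairpin is an exact inverted repeat, so its mature also
maps antisense onto the complementary arm; sense and mirror placements
are indistinguishable by every criterion. Accepted precursors therefore
claim their genomic span (± 3 nt, both strands) and later placements
inside a claimed span are skipped, yielding exactly one call per
hairpin. Truth recovery is scored at hairpin resolution (identical
mature sequence + locus overlap, strand not compared).

Families: greedy incremental clustering seeded by the most-supported
call, joining at ≥ 0.90 best-offset ungapped identity
(matches / shorter length); conserved reference family names override
cluster names and novel members of such families are relabelled novel
isoforms. Genomic context uses precedence CDS > UTR > intron over a
GFF3 annotation, intergenic otherwise; tandem clusters chain loci with
gaps ≤ 10 kb.

## Targets

The miRNA is aligned antiparallel at every transcript offset with at
most one 1-nt gap on either strand. Per-position penalties (mismatch
1.0, G:U 0.5, gap 2.0; doubled at alignment positions 2–13) follow the
default conventions of plant target-prediction servers; only the ≤ 2.5
reporting cutoff is fixed by the method, so the whole weight table is a
config object. Positions are 1-based indices into the pairing string. A
non-match at positions 10–11 → translational repression, else cleavage.
Target-site accessibility (opening energy) is out of scope of the
default pipeline; no crude proxy is enabled by default.

## Expression

Median-of-ratios size factors over rows positive in all samples
(pseudo-count mode for degenerate fixtures); cross-checked in the tests
against an independent implementation. Abundance categories use
order-of-magnitude breaks [10, 100, 1000, 10000) — the five-level
scheme is standard, the breakpoints are a documented package choice.
Tissue calls: below-detection (< 10 normalized everywhere), specific
(top share ≥ 0.90 and all other tissues < 10), preferential (top ≥ 2×
second), else ubiquitous; the ranking statistic behind the published
scheme is not recoverable, so these three knobs are exposed in config
and flagged as a reconstruction in outputs. ΔΔC_T follows Livak: ΔCT =
CT_target − CT_reference per sample, ΔΔCT vs a calibrator sample, RQ =
2^−ΔΔCT, replicate SD over paired technical replicates propagated to RQ
by the delta method. Platform correlation is Pearson on log2(x + 1)
sequencing values vs log2 RQ, both on the calibrator-relative scale.

## Problem sizes and determinism

The study conditions are 100 kb / 20 hairpins / 3 tissues — large
enough that every profile shape, both arms and both strands occur, small
enough that a full run folds ~30 windows plus 99 shuffles for each of
the ~20 accepted candidates. One master seed derives every stage seed
(generator, per-tissue read streams, per-locus shuffle seeds via CRC of
the locus key), so identical configurations give byte-identical outputs;
the run manifest records config and SHA-256 of every file. The two DP
kernels are JIT-compiled with numba; their semantics are fixed by the
brute-force oracle tests.

## Known limitations

- The energy table is a reduced model: no dangling ends, coaxial
  stacking, special tetraloops or pseudoknots; absolute MFEs differ
  from full thermodynamic folders by a few kcal/mol.
- Exact-match genome mapping only; real pipelines tolerate mismatches
  and handle multi-mapping heuristically.
- Strand of a perfectly self-complementary hairpin is unidentifiable
  (see above); real, imperfect stems do not have this degeneracy.
- The conserved/novel split assumes the screens run before miRBase
  matching; tags matching both a screen and a known mature are counted
  as screened.
- qPCR validation data are simulated from the sequencing values by an
  explicit CT model; the correlation demonstrates the ΔΔC_T arithmetic
  and the comparison pathway, not platform concordance of real assays.
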