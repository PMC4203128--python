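"""Novel miRNA discovery from genome-mapped small-RNA tags.

Tags surviving the reference screens are mapped to the genome (exact
full-length matches, both strands), a candidate precursor window of 250 bp
is excised around each locus, folded, and pushed through a deterministic
pass/fail checklist of plant pre-miRNA criteria:

``arm``            mature lies wholly within one stem arm, not the loop
``no_bifurcation`` a single hairpin loop between mature 5' and star 3'
``overhang_star``  a star segment pairing the mature with 2-nt 3' overhangs
                   can be derived from the fold
``duplex14``       >= 14 paired positions between mature and star
``len_diff6``      mature/star length difference <= 6 nt
``randfold``       dinucleotide-shuffle fold-stability P-value <= 0.05
``dicer``          >= 50% of locus reads share the mature 5' end
``min_reads``      >= 10 reads supporting the mature across samples

A candidate is accepted iff all eight verdicts pass; star-read evidence is
recorded as a confidence flag, not a gate. Accepted matures are clustered
into families by greedy sequence identity, and each call is placed into its
genomic context (CDS/UTR/intron/intergenic) and tandem clusters.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

from ._seq import revcomp, to_dna
from .preprocess import UniqueTag
from .structure import FoldResult, fold_energy, fold_maxpair, parse_hairpin, shuffle_pvalue

__all__ = [
    "GenomeLocus",
    "LocusTag",
    "PrecursorCandidate",
    "MiRNACall",
    "FamilyAssignment",
    "DiscoveryThresholds",
    "VERDICT_KEYS",
    "map_tags_to_genome",
    "excise_precursors",
    "evaluate_candidate",
    "discover_novel",
    "cluster_families",
    "annotate_genomic_context",
    "parse_gff3",
]

VERDICT_KEYS = (
    "arm",
    "duplex14",
    "no_bifurcation",
    "overhang_star",
    "len_diff6",
    "randfold",
    "dicer",
    "min_reads",
)


@dataclass(frozen=True)
class GenomeLocus:
    """0-based half-open genomic interval with strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid locus {self}")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class LocusTag:
    """A tag placed inside a precursor window (window coordinates, 5'->3'
    in the orientation of the excised sequence)."""

    tag: UniqueTag
    offset: int  # 5' start of the tag within the window


@dataclass
class PrecursorCandidate:
    locus: GenomeLocus  # excised window, genomic coordinates
    seq: str  # window sequence, 5'->3' (revcomp'ed for minus strand)
    mature_seq: str
    mature_offset: int
    fold: FoldResult | None = None
    star_seq: str | None = None
    star_offset: int | None = None
    duplex_pairs: int = 0
    len_diff: int | None = None
    shuffle_p: float | None = None
    dicer_consistency: float | None = None
    total_count: int = 0
    verdicts: dict = field(default_factory=dict)
    accepted: bool = False
    star_evidence: bool = False
    mfe: float | None = None

    @property
    def rejection_reasons(self) -> list:
        """Verdict keys that measurably failed (skipped checks excluded)."""
        return [k for k in VERDICT_KEYS if self.verdicts.get(k) is False]


@dataclass
class MiRNACall:
    id: str
    seq: str
    class_: str  # conserved | novel | novel_isoform
    family: str
    loci: list
    counts: dict
    precursor: PrecursorCandidate | None = None

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class FamilyAssignment:
    family_id: str
    members: list  # MiRNACall ids
    consensus: str


@dataclass
class DiscoveryThresholds:
    window: int = 250
    margin: int = 20
    max_loci: int = 15
    min_duplex: int = 14
    max_len_diff: int = 6
    randfold_p: float = 0.05
    n_shuffles: int = 99
    dicer_min: float = 0.5
    min_reads: int = 10
    identity: float = 0.90
    cluster_window: int = 10_000
    fold_mode: str = "energy"  # fold mode for criteria + shuffle test
    always_shuffle: bool = False  # run the shuffle test even on doomed seeds
    seed: int = 7


# ---------------------------------------------------------------------------
# genome mapping


def _find_all(haystack: str, needle: str) -> list:
    out, p = [], haystack.find(needle)
    while p != -1:
        out.append(p)
        p = haystack.find(needle, p + 1)
    return out


def map_tags_to_genome(
    tags: dict, genome: dict, max_loci: int = 15
) -> tuple[dict, set]:
    """Exact full-length placement of tags on both strands.

    Returns (placements: seq -> [GenomeLocus], multimapped: set of seqs with
    more than ``max_loci`` placements, to be excluded from novel prediction).
    """
    placements: dict[str, list] = {}
    multimapped = set()
    for seq in tags:
        q = to_dna(seq)
        qrc = revcomp(q)
        loci = []
        for chrom, cseq in genome.items():
            for p in _find_all(cseq, q):
                loci.append(GenomeLocus(chrom, p, p + len(q), "+"))
            for p in _find_all(cseq, qrc):
                loci.append(GenomeLocus(chrom, p, p + len(q), "-"))
        if len(loci) > max_loci:
            multimapped.add(seq)
        elif loci:
            placements[seq] = loci
    return placements, multimapped


# ---------------------------------------------------------------------------
# precursor excision


def excise_precursors(
    locus: GenomeLocus,
    genome: dict,
    window: int = 250,
    margin: int = 20,
) -> list:
    """Excise up to two candidate precursor windows around a mapped tag:
    one with the tag near the window 5' end (margin bp upstream) and one
    with the tag near the 3' end. Windows are clipped at chromosome bounds
    and dropped when shorter than tag + margin. Minus-strand loci are
    excised as the reverse complement with the tag offset recomputed."""
    chrom_seq = genome[locus.chrom]
    clen = len(chrom_seq)
    taglen = len(locus)
    seeds = []
    spans = [
        (locus.start - margin, locus.start - margin + window),
        (locus.end + margin - window, locus.end + margin),
    ]
    seen = set()
    for lo, hi in spans:
        lo, hi = max(0, lo), min(clen, hi)
        if hi - lo < taglen + margin or not (lo <= locus.start and locus.end <= hi):
            continue
        if (lo, hi) in seen:
            continue
        seen.add((lo, hi))
        raw = chrom_seq[lo:hi]
        if locus.strand == "+":
            seq, offset = raw, locus.start - lo
        else:
            seq, offset = revcomp(raw), hi - locus.end
        mature = seq[offset : offset + taglen]
        seeds.append(
            PrecursorCandidate(
                locus=GenomeLocus(locus.chrom, lo, hi, locus.strand),
                seq=seq,
                mature_seq=mature,
                mature_offset=offset,
            )
        )
    return seeds


# ---------------------------------------------------------------------------
# criteria checklist


def _extrapolated_partner(partner: dict, i: int, mlo: int, mhi: int) -> int | None:
    """Partner of position i, extrapolating along the antiparallel register
    from the nearest paired mature position when i itself is unpaired."""
    if i in partner:
        return partner[i]
    for d in range(1, mhi - mlo):
        for i2 in (i - d, i + d):
            if mlo <= i2 < mhi and i2 in partner:
                return partner[i2] + (i2 - i)
    return None


def evaluate_candidate(
    seed: PrecursorCandidate,
    locus_tags: list,
    thresholds: DiscoveryThresholds | None = None,
) -> PrecursorCandidate:
    """Fill in structural/read-support verdicts for one candidate window.

    ``locus_tags`` is the set of tags mapping inside the window, with their
    window offsets; read counts drive the Dicer-consistency and abundance
    verdicts. The seed must already carry a fold.
    """
    th = thresholds or DiscoveryThresholds()
    if seed.fold is None:
        raise ValueError("seed must be folded before evaluation")
    n = len(seed.seq)
    mlo = seed.mature_offset
    mhi = mlo + len(seed.mature_seq)
    partner = seed.fold.partner()
    verdicts = dict.fromkeys(VERDICT_KEYS, False)

    mature_partners = [partner[i] for i in range(mlo, mhi) if i in partner]
    same_side = mature_partners and (
        all(p >= mhi for p in mature_partners) or all(p < mlo for p in mature_partners)
    )

    # star inference via the 2-nt 3' overhang rule: the star pairs mature
    # positions [mlo, mhi-2) and extends 2 nt past the partner of mlo.
    star_lo = star_hi = None
    p_inner = _extrapolated_partner(partner, mhi - 3, mlo, mhi)
    p_outer = _extrapolated_partner(partner, mlo, mlo, mhi)
    if same_side and p_inner is not None and p_outer is not None:
        lo, hi = p_inner, p_outer + 3
        if 0 <= lo < hi <= n and (hi <= mlo or lo >= mhi):
            star_lo, star_hi = lo, hi

    if star_lo is not None:
        seed.star_seq = seed.seq[star_lo:star_hi]
        seed.star_offset = star_lo
        verdicts["overhang_star"] = True
        span = (min(mlo, star_lo), max(mhi, star_hi))
        anatomy = parse_hairpin(seed.fold, span)
        loop_clear = anatomy.loop_span is None or (
            anatomy.loop_span[1] <= mlo or anatomy.loop_span[0] >= mhi
        )
        verdicts["arm"] = bool(same_side and loop_clear)
        verdicts["no_bifurcation"] = anatomy.n_hairpin_loops == 1
        seed.duplex_pairs = sum(
            1
            for i, j in seed.fold.pairs
            if (mlo <= i < mhi and star_lo <= j < star_hi)
            or (star_lo <= i < star_hi and mlo <= j < mhi)
        )
        verdicts["duplex14"] = seed.duplex_pairs >= th.min_duplex
        seed.len_diff = abs(len(seed.mature_seq) - (star_hi - star_lo))
        verdicts["len_diff6"] = seed.len_diff <= th.max_len_diff

    # Dicer-processing consistency: reads at the locus sharing the mature 5' end
    total_reads = sum(lt.tag.total for lt in locus_tags)
    in_register = sum(lt.tag.total for lt in locus_tags if lt.offset == mlo)
    seed.dicer_consistency = in_register / total_reads if total_reads else 0.0
    verdicts["dicer"] = seed.dicer_consistency >= th.dicer_min

    seed.total_count = sum(
        lt.tag.total for lt in locus_tags if lt.tag.seq == seed.mature_seq
    )
    verdicts["min_reads"] = seed.total_count >= th.min_reads

    if star_lo is not None:
        seed.star_evidence = any(
            abs(lt.offset - star_lo) <= 1
            and abs(len(lt.tag.seq) - (star_hi - star_lo)) <= 2
            for lt in locus_tags
        )

    # shuffle-based fold-stability significance on the excised window: the
    # costliest criterion, evaluated last and only when every other verdict
    # already passes (a skipped test is recorded as None, never as a pass)
    others_pass = all(verdicts[k] for k in VERDICT_KEYS if k != "randfold")
    if others_pass or th.always_shuffle:
        rf_seed = (
            zlib.crc32(
                f"{seed.locus.chrom}:{seed.locus.start}:{seed.locus.strand}".encode()
            )
            ^ th.seed
        ) & 0x7FFFFFFF
        st = shuffle_pvalue(
            seed.seq, n_shuffles=th.n_shuffles, mode=th.fold_mode, rng_seed=rf_seed
        )
        seed.shuffle_p = st.p_value
        verdicts["randfold"] = st.p_value <= th.randfold_p
    else:
        verdicts["randfold"] = None

    seed.verdicts = verdicts
    seed.accepted = all(v is True for v in verdicts.values())
    if seed.accepted and star_lo is not None:
        lo, hi = min(mlo, star_lo), max(mhi, star_hi)
        seed.mfe = fold_energy(seed.seq[lo:hi]).score
    return seed


def fold_candidate(
    seed: PrecursorCandidate, mode: str = "energy"
) -> PrecursorCandidate:
    seed.fold = fold_energy(seed.seq) if mode == "energy" else fold_maxpair(seed.seq)
    return seed


# ---------------------------------------------------------------------------
# discovery driver


def discover_novel(
    tags: dict,
    genome: dict,
    thresholds: DiscoveryThresholds | None = None,
) -> tuple[list, list]:
    """Predict novel miRNAs from a merged tag table.

    Returns (calls, all evaluated candidates). Tags are processed in
    decreasing order of read support so that mature strands claim their
    precursors before star/offset variants of the same hairpin are visited;
    tags whose every placement falls inside an already-claimed precursor
    span are skipped.
    """
    th = thresholds or DiscoveryThresholds()
    placements, _multi = map_tags_to_genome(tags, genome, max_loci=th.max_loci)

    # per-chromosome index of placements for locus-tag lookup
    by_chrom: dict[str, list] = {}
    for seq, loci in placements.items():
        for loc in loci:
            by_chrom.setdefault(loc.chrom, []).append((loc, tags[seq]))

    # accepted precursor spans claim their locus on BOTH strands: a hairpin
    # is an inverted repeat, so its mature also maps antisense onto the
    # complementary arm, and that mirror placement is the same gene
    claimed: dict[str, list] = {}

    def _is_claimed(loc: GenomeLocus) -> bool:
        for lo, hi in claimed.get(loc.chrom, []):
            if loc.start >= lo and loc.end <= hi:
                return True
        return False

    order = sorted(placements, key=lambda s: (-tags[s].total, s))
    calls: list[MiRNACall] = []
    candidates: list[PrecursorCandidate] = []
    by_seq: dict[str, MiRNACall] = {}

    for seq in order:
        loci = [l for l in placements[seq] if not _is_claimed(l)]
        if not loci:
            continue
        for locus in loci:
            if _is_claimed(locus):
                continue
            accepted = None
            for seed in excise_precursors(locus, genome, th.window, th.margin):
                w = seed.locus
                locus_tags = []
                for loc, tag in by_chrom.get(w.chrom, []):
                    if loc.strand == w.strand and loc.start >= w.start and loc.end <= w.end:
                        off = (
                            loc.start - w.start
                            if w.strand == "+"
                            else w.end - loc.end
                        )
                        locus_tags.append(LocusTag(tag=tag, offset=off))
                fold_candidate(seed, th.fold_mode)
                evaluate_candidate(seed, locus_tags, th)
                candidates.append(seed)
                if seed.accepted:
                    accepted = seed
                    break
            if accepted is not None:
                w = accepted.locus
                slo = min(accepted.mature_offset, accepted.star_offset)
                shi = max(
                    accepted.mature_offset + len(accepted.mature_seq),
                    accepted.star_offset + len(accepted.star_seq),
                )
                if w.strand == "+":
                    g = (w.start + slo, w.start + shi)
                else:
                    g = (w.end - shi, w.end - slo)
                # pad by 3 nt: the antisense mirror placement of the mature
                # overhangs the star span by the 2-nt duplex offset
                claimed.setdefault(w.chrom, []).append((g[0] - 3, g[1] + 3))
                if seq in by_seq:
                    by_seq[seq].loci.append(locus)
                else:
                    call = MiRNACall(
                        id="",
                        seq=seq,
                        class_="novel",
                        family="unassigned",
                        loci=[locus],
                        counts=dict(tags[seq].counts),
                        precursor=accepted,
                    )
                    by_seq[seq] = call
                    calls.append(call)
    for i, call in enumerate(sorted(calls, key=lambda c: (-c.total, c.seq)), 1):
        call.id = f"novmiR-{i:03d}"
    return calls, candidates


# ---------------------------------------------------------------------------
# family clustering


def _best_offset_identity(a: str, b: str) -> float:
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    best = 0
    for off in range(len(long_) - len(short) + 1):
        m = sum(x == y for x, y in zip(short, long_[off : off + len(short)]))
        best = max(best, m)
    return best / len(short)


def cluster_families(calls: list, identity: float = 0.90) -> list:
    """Greedy incremental clustering of calls into families.

    Calls sorted by (total count desc, seq asc); the first unassigned call
    seeds a family and later calls join the first seed they match at
    >= ``identity`` best-offset ungapped identity (matches / length of the
    shorter sequence). A family containing conserved members keeps the
    conserved reference family name, and novel calls in such a family are
    relabelled novel isoforms.
    """
    ordered = sorted(calls, key=lambda c: (-c.total, c.seq))
    seeds: list[tuple[MiRNACall, list]] = []
    for call in ordered:
        joined = False
        for seed_call, members in seeds:
            if _best_offset_identity(call.seq, seed_call.seq) >= identity:
                members.append(call)
                joined = True
                break
        if not joined:
            seeds.append((call, [call]))
    assignments = []
    novel_counter = 0
    for seed_call, members in seeds:
        conserved_fams = [
            m.family
            for m in members
            if m.class_ == "conserved" and m.family != "unassigned"
        ]
        if conserved_fams:
            fam_id = conserved_fams[0]
            for m in members:
                if m.class_ == "novel":
                    m.class_ = "novel_isoform"
                m.family = fam_id
        else:
            novel_counter += 1
            fam_id = f"novFam-{novel_counter:03d}"
            for m in members:
                m.family = fam_id
        assignments.append(
            FamilyAssignment(
                family_id=fam_id,
                members=[m.id for m in members],
                consensus=_consensus([m.seq for m in members], seed_call.seq),
            )
        )
    return assignments


def _consensus(seqs: list, seed: str) -> str:
    """Majority base per column, members aligned to the seed at their best
    ungapped offset."""
    cols: list[dict] = [dict() for _ in seed]
    for s in seqs:
        short, long_ = (s, seed) if len(s) <= len(seed) else (seed, s)
        best_off, best_m = 0, -1
        for off in range(len(long_) - len(short) + 1):
            m = sum(x == y for x, y in zip(short, long_[off : off + len(short)]))
            if m > best_m:
                best_m, best_off = m, off
        if len(s) <= len(seed):
            for i, base in enumerate(s):
                cols[best_off + i][base] = cols[best_off + i].get(base, 0) + 1
        else:
            for i in range(len(seed)):
                base = s[best_off + i]
                cols[i][base] = cols[i].get(base, 0) + 1
    return "".join(
        max(sorted(c), key=lambda b: c[b]) if c else "N" for c in cols
    )


# ---------------------------------------------------------------------------
# genomic context + tandem clusters


@dataclass
class GFFFeature:
    chrom: str
    ftype: str
    start: int  # 0-based half-open
    end: int
    strand: str
    attrs: dict


def parse_gff3(path) -> list:
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 at line {lineno}: expected 9 columns")
            try:
                start1, end = int(cols[3]), int(cols[4])
            except ValueError:
                raise ValueError(
                    f"malformed GFF3 at line {lineno}: non-integer coordinates"
                ) from None
            attrs = {}
            for item in cols[8].split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attrs[k] = v
            feats.append(
                GFFFeature(
                    chrom=cols[0],
                    ftype=cols[2],
                    start=start1 - 1,
                    end=end,
                    strand=cols[6],
                    attrs=attrs,
                )
            )
    return feats


_UTR_TYPES = {"UTR", "five_prime_UTR", "three_prime_UTR"}


def annotate_genomic_context(
    calls: list,
    annotation: list | str,
    cluster_window: int = 10_000,
) -> tuple[dict, list]:
    """Classify each call's primary locus as CDS/UTR/intron/intergenic
    (precedence CDS > UTR > intron) and find tandem clusters: maximal runs
    of >= 2 miRNA loci on one chromosome with consecutive gaps <=
    ``cluster_window``, flagged same-family or mixed."""
    feats = parse_gff3(annotation) if isinstance(annotation, str) else annotation
    by_type: dict[str, list] = {}
    for f in feats:
        key = (
            "CDS"
            if f.ftype == "CDS"
            else "UTR"
            if f.ftype in _UTR_TYPES
            else "gene"
            if f.ftype in ("gene", "mRNA")
            else None
        )
        if key:
            by_type.setdefault(key, []).append(f)

    def _overlaps(loc: GenomeLocus, pool: list) -> bool:
        return any(
            f.chrom == loc.chrom and f.start < loc.end and loc.start < f.end
            for f in pool
        )

    contexts = {}
    for call in calls:
        if not call.loci:
            contexts[call.id] = "unplaced"
            continue
        loc = call.loci[0]
        if _overlaps(loc, by_type.get("CDS", [])):
            contexts[call.id] = "CDS"
        elif _overlaps(loc, by_type.get("UTR", [])):
            contexts[call.id] = "UTR"
        elif _overlaps(loc, by_type.get("gene", [])):
            contexts[call.id] = "intron"
        else:
            contexts[call.id] = "intergenic"

    # tandem clusters over primary loci
    placed = sorted(
        ((c.loci[0], c) for c in calls if c.loci),
        key=lambda t: (t[0].chrom, t[0].start),
    )
    clusters = []
    run: list = []
    for loc, call in placed:
        if run and loc.chrom == run[-1][0].chrom and loc.start - run[-1][0].end <= cluster_window:
            run.append((loc, call))
        else:
            if len(run) >= 2:
                clusters.append(run)
            run = [(loc, call)]
    if len(run) >= 2:
        clusters.append(run)
    out = []
    for run in clusters:
        fams = {c.family for _, c in run}
        out.append(
            {
                "chrom": run[0][0].chrom,
                "members": [c.id for _, c in run],
                "kind": "same_family" if len(fams) == 1 else "mixed",
            }
        )
    return contexts, out
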