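"""miRNA target prediction by complementarity penalty scoring.

A miRNA is aligned antiparallel against every transcript position; each
miRNA position is scored as perfect match (0), G:U wobble (0.5), mismatch
(1.0) or gap (2.0), with penalties doubled inside the seed-proximal region
(alignment positions 2-13 from the miRNA 5' end). At most one single-nt
gap (on either strand) is explored per alignment. Hits are reported at
penalty <= 2.5; pairing state at miRNA positions 10-11 decides the
predicted silencing mode: any non-match there implies translational
repression, otherwise cleavage.

Pairing strings use '|' match, 'o' G:U wobble, 'x' mismatch, '-' gap.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import SeqIO

from ._seq import to_dna

__all__ = [
    "TargetAlignment",
    "TargetHit",
    "ScoringConfig",
    "score_pairing",
    "find_targets",
    "classify_mode",
]

MATCH, GU, MISMATCH, GAP = "|", "o", "x", "-"

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


@dataclass
class ScoringConfig:
    seed_region: tuple = (2, 13)  # 1-based inclusive alignment positions
    seed_mult: float = 2.0
    w_mismatch: float = 1.0
    w_gu: float = 0.5
    w_gap: float = 2.0
    max_penalty: float = 2.5


@dataclass
class TargetAlignment:
    mirna_id: str
    transcript_id: str
    target_start: int  # 0-based on the transcript
    pairing: str  # one state per alignment position, miRNA 5'->3'

    def __post_init__(self):
        if self.pairing.count(GAP) > 1:
            raise ValueError("invalid alignment: more than one gap")


@dataclass
class TargetHit:
    alignment: TargetAlignment
    penalty: float
    mode: str  # cleavage | translation


def _pair_state(mi: str, tb: str) -> str:
    """Classify the miRNA base / target base opposition (DNA alphabet)."""
    if _COMP.get(mi) == tb:
        return MATCH
    if (mi == "G" and tb == "T") or (mi == "T" and tb == "G"):
        return GU
    return MISMATCH


def score_pairing(pairing: str, config: ScoringConfig | None = None) -> float:
    """Summed penalty of a pairing string; alignment positions are 1-based
    from the miRNA 5' end and the seed-region multiplier applies to
    positions inside ``seed_region`` (inclusive)."""
    cfg = config or ScoringConfig()
    if pairing.count(GAP) > 1:
        raise ValueError("invalid alignment: more than one gap")
    weights = {MATCH: 0.0, GU: cfg.w_gu, MISMATCH: cfg.w_mismatch, GAP: cfg.w_gap}
    lo, hi = cfg.seed_region
    total = 0.0
    for pos, state in enumerate(pairing, start=1):
        w = weights[state]
        if lo <= pos <= hi:
            w *= cfg.seed_mult
        total += w
    return total


def classify_mode(alignment: TargetAlignment, mirna_len: int | None = None) -> str:
    """Cleavage unless any non-match state sits at alignment positions
    10-11 (the central positions opposite the slicing site)."""
    n = mirna_len if mirna_len is not None else len(alignment.pairing)
    if n < 11:
        raise ValueError("miRNA shorter than 11 nt cannot be classified")
    central = alignment.pairing[9:11]
    return "translation" if any(s != MATCH for s in central) else "cleavage"


def _enumerate_alignments(mirna: str, transcript: str):
    """Yield (target_start, pairing string) for every gapless and single-gap
    antiparallel alignment of the miRNA on the transcript.

    Target segments are traversed 3'->5' (reversed) so that index i faces
    miRNA position i."""
    el = len(mirna)
    n = len(transcript)
    # gapless
    for start in range(0, n - el + 1):
        rseg = transcript[start : start + el][::-1]
        yield start, "".join(
            _pair_state(mirna[i], rseg[i]) for i in range(el)
        )
    # single bulged target base: target segment one longer, one base skipped
    for start in range(0, n - el):
        rseg = transcript[start : start + el + 1][::-1]
        for g in range(1, el):
            states = [_pair_state(mirna[i], rseg[i]) for i in range(g)]
            states.append(GAP)
            states.extend(
                _pair_state(mirna[i], rseg[i + 1]) for i in range(g, el)
            )
            yield start, "".join(states)
    # single unpaired miRNA base: target segment one shorter
    for start in range(0, n - el + 2):
        rseg = transcript[start : start + el - 1][::-1]
        for g in range(1, el - 1):
            states = [_pair_state(mirna[i], rseg[i]) for i in range(g)]
            states.append(GAP)
            states.extend(
                _pair_state(mirna[i], rseg[i - 1]) for i in range(g + 1, el)
            )
            yield start, "".join(states)


def find_targets(
    mirna: str,
    transcripts: dict | str,
    max_penalty: float = 2.5,
    mirna_id: str = "query",
    config: ScoringConfig | None = None,
) -> list:
    """Score the miRNA against every transcript position (all offsets,
    optional single gap) and report hits with penalty <= ``max_penalty``,
    best alignment per target start, ordered best-first within each
    transcript (ties to the smaller target start)."""
    cfg = config or ScoringConfig()
    cfg.max_penalty = max_penalty
    if isinstance(transcripts, (str,)):
        transcripts = {
            rec.id: str(rec.seq) for rec in SeqIO.parse(transcripts, "fasta")
        }
    if not transcripts:
        raise ValueError("transcript set is empty")
    q = to_dna(mirna)
    hits = []
    for tid, tseq in transcripts.items():
        tseq = to_dna(tseq)
        best_at: dict[int, tuple[float, str]] = {}
        for start, pairing in _enumerate_alignments(q, tseq):
            pen = score_pairing(pairing, cfg)
            if pen > max_penalty:
                continue
            cur = best_at.get(start)
            if cur is None or pen < cur[0]:
                best_at[start] = (pen, pairing)
        for start in sorted(best_at, key=lambda s: (best_at[s][0], s)):
            pen, pairing = best_at[start]
            aln = TargetAlignment(
                mirna_id=mirna_id,
                transcript_id=tid,
                target_start=start,
                pairing=pairing,
            )
            hits.append(
                TargetHit(
                    alignment=aln,
                    penalty=pen,
                    mode=classify_mode(aln, mirna_len=len(q)),
                )
            )
    return hits


def write_target_table(hits: list, path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna_id\ttranscript_id\ttarget_start\tpenalty\tmode\tpairing\n")
        for h in hits:
            a = h.alignment
            fh.write(
                f"{a.mirna_id}\t{a.transcript_id}\t{a.target_start}\t"
                f"{h.penalty:g}\t{h.mode}\t{a.pairing}\n"
            )
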