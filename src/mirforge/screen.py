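"""Screening of small-RNA tags against structural ncRNA / repeat / organelle
references, and identification of conserved miRNAs by mismatch-bounded
matching to a known mature-miRNA set.

Screens use exact-substring semantics on both strands: a tag matching any
screen sequence is discarded (tallied under the first matching screen).
Conserved calls allow up to ``max_mm`` mismatches in an end-to-end ungapped
alignment against known matures, with the shorter sequence slid over the
longer and overhanging bases counted as mismatches; calls are restricted to
tags of 20-24 nt, mirroring the size range of conserved plant miRNAs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from ._seq import revcomp, to_dna
from .preprocess import UniqueTag

__all__ = [
    "ReferenceSet",
    "ConservedHit",
    "load_reference_fasta",
    "screen_tags",
    "match_known_mirnas",
    "mirna_family",
]

_FAMILY_RE = re.compile(r"(mir[0-9]+)", re.IGNORECASE)


@dataclass
class ReferenceSet:
    """A labelled FASTA reference collection, DNA-normalized."""

    label: str
    sequences: dict  # id -> sequence (DNA)

    def __post_init__(self):
        if not self.sequences:
            raise ValueError(f"reference set {self.label!r} is empty")
        self.sequences = {k: to_dna(v) for k, v in self.sequences.items()}


@dataclass
class ConservedHit:
    tag: UniqueTag
    ref_id: str
    mismatches: int
    family: str


def load_reference_fasta(label: str, path: str | Path) -> ReferenceSet:
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    return ReferenceSet(label=label, sequences=seqs)


def mirna_family(ref_id: str) -> str:
    """Family label: the miR+digits token of a reference id, else 'unassigned'."""
    m = _FAMILY_RE.search(ref_id)
    if m is None:
        return "unassigned"
    token = m.group(1)
    return "miR" + token[3:]


def screen_tags(
    tags: dict, screens: list[ReferenceSet]
) -> tuple[dict, dict]:
    """Partition tags into retained vs discarded-by-screen.

    A tag is discarded iff it occurs as an exact substring of any screen
    sequence on either strand; the tally records the first matching screen.
    """
    if not screens:
        import warnings

        warnings.warn("no screen references supplied; all tags retained")
        return dict(tags), {}
    retained = {}
    tally: dict[str, int] = {s.label: 0 for s in screens}
    for seq, tag in tags.items():
        q = to_dna(seq)
        qrc = revcomp(q)
        hit_label = None
        for ref in screens:
            for ref_seq in ref.sequences.values():
                if q in ref_seq or qrc in ref_seq:
                    hit_label = ref.label
                    break
            if hit_label:
                break
        if hit_label is None:
            retained[seq] = tag
        else:
            tally[hit_label] += 1
    return retained, tally


def _slide_mismatches(a: str, b: str) -> int:
    """Minimum end-to-end mismatches sliding the shorter of a/b over the
    longer; overhanging bases of the longer count as mismatches."""
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    overhang = len(long_) - len(short)
    best = None
    for off in range(overhang + 1):
        mm = overhang + sum(
            x != y for x, y in zip(short, long_[off : off + len(short)])
        )
        if best is None or mm < best:
            best = mm
    return best


def match_known_mirnas(
    tags: dict,
    known: ReferenceSet,
    max_mm: int = 2,
    min_tag_len: int = 20,
    max_tag_len: int = 24,
    max_len_diff: int = 2,
) -> tuple[list[ConservedHit], dict]:
    """Identify conserved miRNAs among tags.

    A tag is conserved iff some known mature within ``max_len_diff`` nt of
    its length aligns with <= ``max_mm`` total mismatches (both strands
    considered). The minimum-mismatch hit is reported; ties break to the
    lexicographically smallest reference id.
    """
    hits = []
    unmatched = {}
    for seq, tag in tags.items():
        q = to_dna(seq)
        if not (min_tag_len <= len(q) <= max_tag_len):
            unmatched[seq] = tag
            continue
        qrc = revcomp(q)
        best: tuple[int, str] | None = None
        for ref_id in sorted(known.sequences):
            ref_seq = known.sequences[ref_id]
            if abs(len(q) - len(ref_seq)) > max_len_diff:
                continue
            mm = min(_slide_mismatches(q, ref_seq), _slide_mismatches(qrc, ref_seq))
            if mm <= max_mm and (best is None or mm < best[0]):
                best = (mm, ref_id)
        if best is None:
            unmatched[seq] = tag
        else:
            hits.append(
                ConservedHit(
                    tag=tag,
                    ref_id=best[1],
                    mismatches=best[0],
                    family=mirna_family(best[1]),
                )
            )
    return hits, unmatched
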