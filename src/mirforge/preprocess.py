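"""Raw small-RNA FASTQ processing: quality filter, adapter/poly-A trimming,
read collapsing and 18-30 nt size selection.

Reads failing the quality rule (more than ``max_low_frac`` of bases below
Phred ``low_q``, or containing N) are dropped; surviving reads are trimmed
of the 3' sequencing adapter and trailing poly-A, collapsed to unique tags
with per-sample counts, and restricted to the 18-30 nt size range retained
for miRNA analysis. Reads without any adapter match are kept untrimmed
(upstream demultiplexing may pre-trim) and tallied separately.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from ._seq import to_rna

__all__ = [
    "RawRead",
    "UniqueTag",
    "LibraryStats",
    "read_fastq",
    "quality_filter",
    "trim_read",
    "collapse_and_size_select",
    "preprocess_fastq",
    "merge_tag_tables",
    "write_tag_table",
    "read_tag_table",
]


@dataclass
class RawRead:
    seq: str
    qual: tuple  # Phred scores per base

    def __post_init__(self):
        if len(self.seq) != len(self.qual):
            raise ValueError("sequence and quality lengths differ")


@dataclass
class UniqueTag:
    """A distinct small-RNA sequence with per-sample read counts."""

    seq: str
    counts: dict = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class LibraryStats:
    sample: str
    raw_reads: int = 0
    discarded_quality: int = 0
    discarded_n: int = 0
    trimmed_away: int = 0
    untrimmed_kept: int = 0
    dropped_size: int = 0
    post_qc_reads: int = 0
    unique_tags: int = 0
    size_histogram: dict = field(default_factory=dict)
    first_nt_histogram: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "sample": self.sample,
            "raw_reads": self.raw_reads,
            "discarded_quality": self.discarded_quality,
            "discarded_n": self.discarded_n,
            "trimmed_away": self.trimmed_away,
            "untrimmed_kept": self.untrimmed_kept,
            "dropped_size": self.dropped_size,
            "post_qc_reads": self.post_qc_reads,
            "unique_tags": self.unique_tags,
            "size_histogram": dict(sorted(self.size_histogram.items())),
            "first_nt_histogram": self.first_nt_histogram,
        }


def read_fastq(path: str | Path) -> Iterator[RawRead]:
    for rec in SeqIO.parse(str(path), "fastq"):
        yield RawRead(str(rec.seq).upper(), tuple(rec.letter_annotations["phred_quality"]))


def quality_filter(
    read: RawRead, max_low_frac: float = 0.30, low_q: int = 20
) -> tuple[bool, str]:
    """Keep/discard decision for one read.

    Discard iff the fraction of bases with Phred < ``low_q`` exceeds
    ``max_low_frac``, the read contains N, or the read is empty.
    Returns (keep, reason).
    """
    if len(read.seq) == 0:
        return False, "empty"
    if "N" in read.seq:
        return False, "N"
    low = sum(q < low_q for q in read.qual)
    if low / len(read.seq) > max_low_frac:
        return False, "low_quality"
    return True, "ok"


def trim_read(
    read: RawRead | str,
    adapter: str,
    min_overlap: int = 6,
    polya_min: int = 8,
) -> str | None:
    """Remove the 3' adapter and any trailing poly-A run.

    The leftmost position where a prefix of ``adapter`` (>= ``min_overlap``
    exact bases, extending to the read 3' end or covering the full adapter)
    matches is trimmed away, then a trailing run of >= ``polya_min`` A's is
    removed. Returns None when nothing remains.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    seq = read.seq if isinstance(read, RawRead) else read
    adapter = adapter.upper()
    la = len(adapter)
    cut = None
    for p in range(len(seq)):
        k = min(la, len(seq) - p)
        if k >= min_overlap and seq[p : p + k] == adapter[:k]:
            cut = p
            break
    trimmed = seq[:cut] if cut is not None else seq
    # poly-A tail
    run = len(trimmed) - len(trimmed.rstrip("A"))
    if run >= polya_min:
        trimmed = trimmed.rstrip("A")
    return trimmed if trimmed else None


def collapse_and_size_select(
    seqs: Iterable[str],
    sample: str,
    min_len: int = 18,
    max_len: int = 30,
) -> tuple[dict, LibraryStats]:
    """Collapse identical trimmed sequences into unique tags, keeping only
    the ``min_len``-``max_len`` size range; histograms are over distinct
    retained tags."""
    counter: Counter = Counter()
    dropped = 0
    n_in = 0
    for s in seqs:
        n_in += 1
        if min_len <= len(s) <= max_len:
            counter[s] += 1
        else:
            dropped += 1
    tags = {s: UniqueTag(seq=s, counts={sample: c}) for s, c in counter.items()}
    stats = LibraryStats(sample=sample)
    stats.dropped_size = dropped
    stats.post_qc_reads = n_in - dropped
    stats.unique_tags = len(tags)
    size_hist: Counter = Counter(len(s) for s in tags)
    first_nt: Counter = Counter(to_rna(s[0]) for s in tags)
    stats.size_histogram = dict(size_hist)
    stats.first_nt_histogram = {b: first_nt.get(b, 0) for b in "ACGU"}
    return tags, stats


def preprocess_fastq(
    path: str | Path,
    sample: str,
    adapter: str,
    max_low_frac: float = 0.30,
    low_q: int = 20,
    min_overlap: int = 6,
    polya_min: int = 8,
    min_len: int = 18,
    max_len: int = 30,
) -> tuple[dict, LibraryStats]:
    """Full per-sample preprocessing: quality filter, trim, collapse."""
    kept_seqs = []
    raw = disc_q = disc_n = trimmed_away = untrimmed = 0
    for read in read_fastq(path):
        raw += 1
        keep, reason = quality_filter(read, max_low_frac=max_low_frac, low_q=low_q)
        if not keep:
            if reason == "N":
                disc_n += 1
            else:
                disc_q += 1
            continue
        t = trim_read(read, adapter, min_overlap=min_overlap, polya_min=polya_min)
        if t is None:
            trimmed_away += 1
            continue
        if t == read.seq:
            untrimmed += 1
        kept_seqs.append(t)
    tags, stats = collapse_and_size_select(
        kept_seqs, sample, min_len=min_len, max_len=max_len
    )
    stats.raw_reads = raw
    stats.discarded_quality = disc_q
    stats.discarded_n = disc_n
    stats.trimmed_away = trimmed_away
    stats.untrimmed_kept = untrimmed
    return tags, stats


def merge_tag_tables(per_sample: dict[str, dict]) -> dict:
    """Merge per-sample tag dicts into one seq -> UniqueTag map preserving
    per-sample counts."""
    merged: dict[str, UniqueTag] = {}
    for sample, tags in per_sample.items():
        for seq, tag in tags.items():
            merged.setdefault(seq, UniqueTag(seq=seq)).counts[sample] = tag.counts[
                sample
            ]
    return merged


def write_tag_table(tags: dict, samples: list, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("seq\t" + "\t".join(samples) + "\n")
        for seq in sorted(tags):
            counts = tags[seq].counts
            fh.write(seq + "\t" + "\t".join(str(counts.get(s, 0)) for s in samples) + "\n")


def read_tag_table(path: str | Path) -> dict:
    tags: dict[str, UniqueTag] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        samples = header[1:]
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            counts = {
                s: int(c) for s, c in zip(samples, parts[1:]) if int(c) > 0
            }
            tags[parts[0]] = UniqueTag(seq=parts[0], counts=counts)
    return tags
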