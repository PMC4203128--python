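"""Synthetic genomes with planted miRNA hairpins and tissue-specific
small-RNA read libraries with known truth.

The generator emulates the statistical structure of a plant small-RNA
sequencing experiment: 18-30 nt inserts dominated by 21/24-nt species with
a 5'-uridine bias, mature >> star abundance, tissue-varying expression,
rRNA/tRNA-like contaminants, and a 3' sequencing adapter on every read.
Background genome sequence is i.i.d. uniform ACGT.

Hairpin construction: for a 5p mature the precursor is
``mature + loop + revcomp(mature) + 2 nt``; the full mature is paired in
the stem and the mature:star duplex carries 2-nt 3' overhangs on both
strands (the overhanging mature bases pair with stem bases just outside
the star span, as in genuine pre-miRNAs). Loop and extension bases are
drawn from {A, C} so they cannot form canonical pairs with each other,
keeping zero-mutation precursors single-hairpin by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from ._seq import revcomp, to_dna
from .discovery import GenomeLocus

__all__ = [
    "PlantedMiRNA",
    "SyntheticConfig",
    "TruthTable",
    "build_hairpin_precursor",
    "plant_genome",
    "simulate_read_libraries",
    "write_genome_fasta",
    "write_truth_gff3",
    "write_truth_tsv",
]

_NT = np.array(list("ACGT"))
# default 3' adapter: Illumina TruSeq small-RNA
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


@dataclass
class PlantedMiRNA:
    id: str
    mature_seq: str
    arm: str  # 5p | 3p
    locus: GenomeLocus  # precursor locus, genomic coordinates
    star_seq: str
    per_tissue_count: dict
    precursor_seq: str = ""
    mature_offset: int = 0  # mature 5' offset within the precursor

    def __post_init__(self):
        if not (20 <= len(self.mature_seq) <= 24):
            raise ValueError("mature length must be 20-24 nt")

    @property
    def mature_locus(self) -> GenomeLocus:
        lo, hi = self.mature_offset, self.mature_offset + len(self.mature_seq)
        if self.locus.strand == "+":
            return GenomeLocus(
                self.locus.chrom, self.locus.start + lo, self.locus.start + hi, "+"
            )
        return GenomeLocus(
            self.locus.chrom, self.locus.end - hi, self.locus.end - lo, "-"
        )


@dataclass
class SyntheticConfig:
    genome_length: int = 100_000
    n_loci: int = 20
    tissues: tuple = ("shoot", "root", "leaf")
    mature_len_choices: tuple = (21, 21, 21, 24, 22, 20)  # 21/24-dominated
    loop_len: int = 8
    flank_len: int = 30
    mutation_rate: float = 0.0
    star_fraction: float = 0.1
    contaminant_fraction: float = 0.0
    low_quality_fraction: float = 0.0
    adapter_seq: str = DEFAULT_ADAPTER
    end_jitter_prob: float = 0.0
    read_length: int = 36
    count_mode: str = "config"  # config | lognormal
    count_profiles: tuple | None = None  # explicit per-locus tissue->count maps
    lognormal_mu: float = 4.0
    lognormal_sigma: float = 1.2
    seed: int = 0

    def __post_init__(self):
        for p in (
            self.mutation_rate,
            self.star_fraction,
            self.contaminant_fraction,
            self.end_jitter_prob,
            self.low_quality_fraction,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities/fractions must lie in [0, 1]")
        span = max(self.mature_len_choices) * 2 + self.loop_len + 2
        if self.n_loci * (2 * self.flank_len + span) > self.genome_length:
            raise ValueError("genome too short for requested number of loci")

    @classmethod
    def from_file(cls, path: str | Path) -> "SyntheticConfig":
        text = Path(path).read_text()
        doc = (
            json.loads(text)
            if str(path).endswith(".json")
            else yaml.safe_load(text)
        )
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("tissues", "mature_len_choices", "count_profiles"):
            if key in doc and doc[key] is not None:
                doc[key] = tuple(doc[key])
        return cls(**doc)


@dataclass
class TruthTable:
    records: list = field(default_factory=list)
    contaminant_sources: list = field(default_factory=list)  # (label, seq)

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("truth ids must be unique")


# ---------------------------------------------------------------------------
# hairpin construction


def build_hairpin_precursor(
    mature: str,
    arm: str = "5p",
    loop_len: int = 8,
    mutation_rate: float = 0.0,
    rng_seed: int = 0,
) -> tuple[str, str]:
    """Build a pre-miRNA around ``mature`` and derive its star sequence.

    Returns (precursor, star), DNA alphabet. With ``mutation_rate`` 0 the
    stem is perfectly paired; otherwise stem positions are perturbed into
    G:T wobbles or single mismatches on the non-mature arm, capped at 20%
    of stem pairs.
    """
    mature = to_dna(mature)
    if not (20 <= len(mature) <= 24):
        raise ValueError("mature length must be 20-24 nt")
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3 (folding cannot close the loop)")
    if arm not in ("5p", "3p"):
        raise ValueError("arm must be '5p' or '3p'")
    rng = np.random.default_rng(rng_seed)
    el = len(mature)
    loop = "".join(rng.choice(["A", "C"], size=loop_len))
    comp_arm = list(revcomp(mature))
    # stem imperfections: mutate complementary-arm bases opposite mature
    if mutation_rate > 0:
        max_mut = int(0.2 * el)
        idx = [i for i in range(el) if rng.random() < mutation_rate][:max_mut]
        for i in idx:  # i indexes the mature; opposite base is comp_arm[el-1-i]
            mbase = mature[i]
            if mbase == "T" and rng.random() < 0.5:
                comp_arm[el - 1 - i] = "G"  # T:G wobble
            elif mbase == "G" and rng.random() < 0.5:
                comp_arm[el - 1 - i] = "T"  # G:T wobble
            else:
                cur = comp_arm[el - 1 - i]
                choices = [b for b in "ACGT" if b != cur]
                comp_arm[el - 1 - i] = choices[rng.integers(3)]
    comp_arm = "".join(comp_arm)
    ext = "".join(rng.choice(["A", "C"], size=2))
    if arm == "5p":
        precursor = mature + loop + comp_arm + ext
        star = (comp_arm + ext)[2:]
    else:
        precursor = comp_arm + loop + mature
        star = comp_arm[2:] + loop[:2]
    return precursor, star


# ---------------------------------------------------------------------------
# genome planting


def _default_profile(i: int, tissues: tuple) -> dict:
    """Deterministic per-tissue count profiles cycling over three shapes:
    uniform, single-tissue specific, and graded."""
    t = len(tissues)
    kind = i % 3
    if kind == 0:
        return {ts: 50 for ts in tissues}
    if kind == 1:
        target = tissues[i % t]
        return {ts: (120 if ts == target else 0) for ts in tissues}
    return {ts: 20 * (((i + k) % t) + 1) for k, ts in enumerate(tissues)}


def plant_genome(config: SyntheticConfig) -> tuple[dict, TruthTable]:
    """Generate a genome with ``n_loci`` non-overlapping planted hairpins.

    Background is i.i.d. uniform ACGT; each precursor overwrites the
    background at its locus (minus-strand loci carry the reverse
    complement). Raises when the requested loci cannot be placed without
    overlap, reporting how many fit.
    """
    rng = np.random.default_rng(config.seed)
    genome = rng.choice(_NT, size=config.genome_length)
    records = []
    occupied: list[tuple[int, int]] = []
    for i in range(config.n_loci):
        mlen = int(
            config.mature_len_choices[i % len(config.mature_len_choices)]
        )
        # 5'-uridine bias of plant matures
        first = "T" if rng.random() < 0.6 else str(rng.choice(_NT))
        mature = first + "".join(rng.choice(_NT, size=mlen - 1))
        arm = "5p" if i % 2 == 0 else "3p"
        precursor, star = build_hairpin_precursor(
            mature,
            arm=arm,
            loop_len=config.loop_len,
            mutation_rate=config.mutation_rate,
            rng_seed=int(rng.integers(2**31)),
        )
        placed = False
        for _attempt in range(200):
            pos = int(
                rng.integers(
                    config.flank_len,
                    config.genome_length - len(precursor) - config.flank_len,
                )
            )
            lo, hi = pos - config.flank_len, pos + len(precursor) + config.flank_len
            if all(hi <= a or b <= lo for a, b in occupied):
                occupied.append((lo, hi))
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place locus {i + 1} without overlap; {len(records)} fit"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        ins = precursor if strand == "+" else revcomp(precursor)
        genome[pos : pos + len(precursor)] = list(ins)
        locus = GenomeLocus("chr1", pos, pos + len(precursor), strand)
        if config.count_mode == "lognormal":
            counts = {
                ts: int(
                    np.round(
                        rng.lognormal(config.lognormal_mu, config.lognormal_sigma)
                    )
                )
                for ts in config.tissues
            }
        elif config.count_profiles is not None:
            counts = dict(config.count_profiles[i % len(config.count_profiles)])
        else:
            counts = _default_profile(i, config.tissues)
        mature_offset = 0 if arm == "5p" else len(precursor) - mlen
        records.append(
            PlantedMiRNA(
                id=f"planted-{i + 1:03d}",
                mature_seq=mature,
                arm=arm,
                locus=locus,
                star_seq=star,
                per_tissue_count=counts,
                precursor_seq=precursor,
                mature_offset=mature_offset,
            )
        )
    contaminants = []
    if config.contaminant_fraction > 0:
        for label, length in (("rRNA-like", 1200), ("tRNA-like", 80)):
            contaminants.append(
                (label, "".join(rng.choice(_NT, size=length)))
            )
    return {"chr1": "".join(genome)}, TruthTable(
        records=records, contaminant_sources=contaminants
    )


# ---------------------------------------------------------------------------
# read simulation


def _phred33(qs: list) -> str:
    return "".join(chr(q + 33) for q in qs)


def simulate_read_libraries(
    truth: TruthTable,
    config: SyntheticConfig,
    outdir: str | Path,
) -> dict:
    """Write one FASTQ per tissue; returns tissue -> path.

    Every read is insert + 3' adapter, truncated to ``read_length`` and
    padded with adapter-run-on A's if shorter; base qualities are constant
    Q30 except for an optional injected low-quality read fraction. Mature
    reads appear at their configured per-tissue counts, star reads at
    ``star_fraction`` of the mature count, contaminant reads as random
    18-30 nt substrings of the contaminant sources.
    """
    if not truth.records and config.contaminant_fraction == 0:
        raise ValueError("nothing to simulate: empty truth and no contaminants")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for rec in truth.records:
        unknown = set(rec.per_tissue_count) - set(config.tissues)
        if unknown:
            raise ValueError(f"unknown tissue labels {sorted(unknown)} in {rec.id}")
    paths = {}
    for t_idx, tissue in enumerate(config.tissues):
        rng = np.random.default_rng((config.seed + 1) * 10_007 + t_idx)
        inserts: list[str] = []
        for rec in truth.records:
            n_mature = rec.per_tissue_count.get(tissue, 0)
            n_star = int(round(config.star_fraction * n_mature))
            for src, count in ((True, n_mature), (False, n_star)):
                base = rec.mature_seq if src else rec.star_seq
                off = (
                    rec.mature_offset
                    if src
                    else rec.precursor_seq.find(base)
                )
                for _ in range(count):
                    ins = base
                    if config.end_jitter_prob > 0:
                        lo, hi = off, off + len(base)
                        if rng.random() < config.end_jitter_prob:
                            lo += int(rng.integers(-1, 2))
                        if rng.random() < config.end_jitter_prob:
                            hi += int(rng.integers(-1, 2))
                        lo = max(0, lo)
                        hi = min(len(rec.precursor_seq), max(lo + 18, hi))
                        ins = rec.precursor_seq[lo:hi]
                    inserts.append(ins)
        n_planted = len(inserts)
        n_cont = int(round(config.contaminant_fraction * n_planted))
        if config.contaminant_fraction > 0 and not truth.contaminant_sources:
            raise ValueError("contaminant_fraction > 0 but no contaminant sources")
        for _ in range(n_cont):
            label, src = truth.contaminant_sources[
                int(rng.integers(len(truth.contaminant_sources)))
            ]
            length = int(rng.integers(18, 31))
            p = int(rng.integers(0, len(src) - length + 1))
            inserts.append(src[p : p + length])
        path = outdir / f"{tissue}.fastq"
        with open(path, "w") as fh:
            for ridx, ins in enumerate(inserts):
                read = (ins + config.adapter_seq)[: config.read_length]
                if len(read) < config.read_length:
                    read = read + "A" * (config.read_length - len(read))
                if (
                    config.low_quality_fraction > 0
                    and rng.random() < config.low_quality_fraction
                ):
                    n_low = int(0.4 * len(read))
                    quals = [10] * n_low + [30] * (len(read) - n_low)
                else:
                    quals = [30] * len(read)
                fh.write(
                    f"@{tissue}_{ridx + 1}\n{read}\n+\n{_phred33(quals)}\n"
                )
        paths[tissue] = path
    return paths


# ---------------------------------------------------------------------------
# serialization


def write_genome_fasta(genome: dict, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_truth_gff3(truth: TruthTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in truth.records:
            loc = rec.locus
            fh.write(
                "\t".join(
                    [
                        loc.chrom,
                        "mirforge_synthetic",
                        "miRNA_primary_transcript",
                        str(loc.start + 1),
                        str(loc.end),
                        ".",
                        loc.strand,
                        ".",
                        f"ID={rec.id};arm={rec.arm}",
                    ]
                )
                + "\n"
            )
            ml = rec.mature_locus
            fh.write(
                "\t".join(
                    [
                        ml.chrom,
                        "mirforge_synthetic",
                        "miRNA",
                        str(ml.start + 1),
                        str(ml.end),
                        ".",
                        ml.strand,
                        ".",
                        f"ID={rec.id}.mature;Parent={rec.id}",
                    ]
                )
                + "\n"
            )


def write_truth_tsv(truth: TruthTable, tissues: tuple, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "id\tmature_seq\tarm\tchrom\tstart\tend\tstrand\tstar_seq\t"
            + "\t".join(tissues)
            + "\n"
        )
        for rec in truth.records:
            loc = rec.locus
            fh.write(
                "\t".join(
                    [
                        rec.id,
                        rec.mature_seq,
                        rec.arm,
                        loc.chrom,
                        str(loc.start),
                        str(loc.end),
                        loc.strand,
                        rec.star_seq,
                    ]
                    + [str(rec.per_tissue_count.get(t, 0)) for t in tissues]
                )
                + "\n"
            )
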