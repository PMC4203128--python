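"""End-to-end pipeline orchestration: simulate -> preprocess -> screen ->
conserved matching -> novel discovery -> families -> targets -> expression,
with a machine-readable run manifest and summary.

A single master seed in the run configuration derives every stage seed
deterministically, so identical configurations produce byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ._seq import gc_fraction, to_rna
from . import discovery as disc
from . import expression as expr
from . import preprocess as prep
from . import screen as scr
from . import synthetic as syn
from . import targets as tgt

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "summarize_calls"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: str):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    synthetic: syn.SyntheticConfig = field(default_factory=syn.SyntheticConfig)
    thresholds: disc.DiscoveryThresholds = field(
        default_factory=disc.DiscoveryThresholds
    )
    # optional external references (paths); absent -> stage degrades gracefully
    known_mirnas: str | None = None
    screens: tuple = ()  # ((label, path), ...)
    transcripts: str | None = None
    annotation: str | None = None
    detection_min: float = 10.0
    pref_ratio: float = 2.0
    spec_frac: float = 0.90
    max_penalty: float = 2.5
    run_targets: bool = True
    seed: int = 0

    def __post_init__(self):
        # single-seed policy: stage seeds derive from the master seed
        self.synthetic = dataclasses.replace(self.synthetic, seed=self.seed * 3 + 1)
        self.thresholds = dataclasses.replace(
            self.thresholds, seed=(self.seed * 3 + 2) & 0x7FFFFFFF
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(doc)
        if "synthetic" in kwargs:
            kwargs["synthetic"] = syn.SyntheticConfig(**kwargs["synthetic"])
        if "thresholds" in kwargs:
            kwargs["thresholds"] = disc.DiscoveryThresholds(**kwargs["thresholds"])
        if "screens" in kwargs:
            kwargs["screens"] = tuple(tuple(x) for x in kwargs["screens"])
        return cls(**kwargs)

    def preflight(self) -> None:
        for label, p in (
            ("known_mirnas", self.known_mirnas),
            ("transcripts", self.transcripts),
            ("annotation", self.annotation),
        ):
            if p is not None and not Path(p).exists():
                raise PipelineError("preflight", f"missing {label} file: {p}")
        for label, p in self.screens:
            if not Path(p).exists():
                raise PipelineError("preflight", f"missing screen file {label}: {p}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _json_default(o):
    if dataclasses.is_dataclass(o) and not isinstance(o, type):
        return dataclasses.asdict(o)
    if isinstance(o, Path):
        return str(o)
    if isinstance(o, tuple):
        return list(o)
    raise TypeError(f"not serializable: {type(o)}")


def summarize_calls(
    calls: list, matrix: expr.CountMatrix, detection_min: float = 10.0
) -> dict:
    """Descriptive statistics over the final call set: size and 5'-nt
    histograms, GC% distribution, precursor MFE distribution with the
    fraction below -20 kcal/mol, and the tissue-sharing breakdown
    (presence = normalized count >= ``detection_min``)."""
    sizes: dict[int, int] = {}
    first_nt = {b: 0 for b in "ACGU"}
    gc = []
    mfe = []
    for c in calls:
        sizes[len(c.seq)] = sizes.get(len(c.seq), 0) + 1
        first_nt[to_rna(c.seq[0])] += 1
        gc.append(round(100.0 * gc_fraction(c.seq), 2))
        if c.precursor is not None and c.precursor.mfe is not None:
            mfe.append(c.precursor.mfe)
    sharing = {"all": 0, "multi": 0, "single": 0, "none": 0}
    if len(calls):
        norm = matrix.normalized
        n_tissues = norm.shape[1]
        for c in calls:
            if c.id not in norm.index:
                continue
            present = int((norm.loc[c.id] >= detection_min).sum())
            if present == n_tissues:
                sharing["all"] += 1
            elif present > 1:
                sharing["multi"] += 1
            elif present == 1:
                sharing["single"] += 1
            else:
                sharing["none"] += 1
    return {
        "n_calls": len(calls),
        "size_histogram": dict(sorted(sizes.items())),
        "first_nt_histogram": first_nt,
        "gc_percent": gc,
        "mfe_kcal_mol": mfe,
        "mfe_below_minus20_fraction": (
            sum(1 for m in mfe if m < -20.0) / len(mfe) if mfe else None
        ),
        "tissue_sharing": sharing,
    }


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute all stages; returns the run summary dict.

    Writes per-stage outputs plus ``summary.json`` and ``manifest.json``
    under ``outdir``. Any stage error aborts with the stage name and cause
    before later outputs are produced.
    """
    config.preflight()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": {}}
    tissues = list(config.synthetic.tissues)

    # --- simulate -----------------------------------------------------
    try:
        genome, truth = syn.plant_genome(config.synthetic)
        fastqs = syn.simulate_read_libraries(truth, config.synthetic, outdir / "reads")
        syn.write_genome_fasta(genome, outdir / "genome.fa")
        syn.write_truth_gff3(truth, outdir / "truth.gff3")
        syn.write_truth_tsv(truth, config.synthetic.tissues, outdir / "truth.tsv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("simulate", str(exc)) from exc
    summary["stages"]["simulate"] = {
        "n_loci": len(truth.records),
        "tissues": tissues,
    }

    # --- preprocess ---------------------------------------------------
    try:
        per_sample = {}
        stats_all = {}
        for tissue in tissues:
            tags, stats = prep.preprocess_fastq(
                fastqs[tissue], tissue, adapter=config.synthetic.adapter_seq
            )
            per_sample[tissue] = tags
            stats_all[tissue] = stats.as_dict()
        merged = prep.merge_tag_tables(per_sample)
        prep.write_tag_table(merged, tissues, outdir / "tags.tsv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("preprocess", str(exc)) from exc
    summary["stages"]["preprocess"] = stats_all

    # --- reference screens --------------------------------------------
    screens = [scr.load_reference_fasta(lbl, p) for lbl, p in config.screens]
    if screens:
        retained, tally = scr.screen_tags(merged, screens)
    else:
        retained, tally = dict(merged), {}
    summary["stages"]["screen"] = {
        "tags_in": len(merged),
        "tags_retained": len(retained),
        "discard_tally": tally,
    }

    # --- conserved matching -------------------------------------------
    conserved_calls: list = []
    if config.known_mirnas:
        known = scr.load_reference_fasta("known_miRNA", config.known_mirnas)
        hits, unmatched = scr.match_known_mirnas(retained, known)
        for i, h in enumerate(sorted(hits, key=lambda h: h.ref_id), 1):
            conserved_calls.append(
                disc.MiRNACall(
                    id=f"cons-{i:03d}",
                    seq=h.tag.seq,
                    class_="conserved",
                    family=h.family,
                    loci=[],
                    counts=dict(h.tag.counts),
                )
            )
    else:
        unmatched = retained
    summary["stages"]["conserved"] = {"n_conserved": len(conserved_calls)}

    # --- novel discovery ----------------------------------------------
    try:
        novel_calls, candidates = disc.discover_novel(
            unmatched, genome, config.thresholds
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("discover", str(exc)) from exc
    rejected = [c for c in candidates if not c.accepted]
    reason_tally: dict[str, int] = {}
    for c in rejected:
        for r in c.rejection_reasons:
            reason_tally[r] = reason_tally.get(r, 0) + 1
    summary["stages"]["discover"] = {
        "candidates_evaluated": len(candidates),
        "novel_accepted": len(novel_calls),
        "rejection_reason_tally": dict(sorted(reason_tally.items())),
    }
    _write_candidate_table(candidates, outdir / "candidates.tsv")
    _write_call_outputs(novel_calls, outdir)

    calls = conserved_calls + novel_calls

    # --- families -----------------------------------------------------
    families = disc.cluster_families(calls, identity=config.thresholds.identity)
    summary["stages"]["families"] = {
        "n_families": len(families),
        "n_multi_member": sum(1 for f in families if len(f.members) > 1),
        "n_novel_isoforms": sum(1 for c in calls if c.class_ == "novel_isoform"),
    }

    # --- genomic context ----------------------------------------------
    if config.annotation:
        contexts, clusters = disc.annotate_genomic_context(
            calls, config.annotation, config.thresholds.cluster_window
        )
        summary["stages"]["context"] = {
            "contexts": contexts,
            "tandem_clusters": clusters,
        }

    # --- targets ------------------------------------------------------
    if config.run_targets and config.transcripts:
        all_hits = []
        for c in calls:
            all_hits.extend(
                tgt.find_targets(
                    c.seq,
                    config.transcripts,
                    max_penalty=config.max_penalty,
                    mirna_id=c.id,
                )
            )
        tgt.write_target_table(all_hits, outdir / "targets.tsv")
        modes = {"cleavage": 0, "translation": 0}
        for h in all_hits:
            modes[h.mode] += 1
        summary["stages"]["targets"] = {"n_hits": len(all_hits), "modes": modes}

    # --- expression ----------------------------------------------------
    try:
        matrix = expr.CountMatrix.from_calls(calls, tissues)
        try:
            matrix.size_factors = expr.estimate_size_factors(matrix)
            pseudo = 0.0
        except ValueError:
            matrix.size_factors = expr.estimate_size_factors(matrix, pseudocount=1.0)
            pseudo = 1.0
        spec_calls, normalizers = expr.rank_tissue_preference(
            matrix,
            detection_min=config.detection_min,
            pref_ratio=config.pref_ratio,
            spec_frac=config.spec_frac,
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("express", str(exc)) from exc
    matrix.normalized.round(4).to_csv(outdir / "normalized.tsv", sep="\t")
    matrix.size_factors.round(6).to_csv(outdir / "size_factors.tsv", sep="\t")
    with open(outdir / "specificity.tsv", "w") as fh:
        fh.write("mirna_id\tcategory\tpreferred_tissue\ttop_fraction\n")
        for s in spec_calls:
            top = max(s.fractions.values()) if s.fractions else 0.0
            fh.write(
                f"{s.mirna_id}\t{s.category}\t{s.preferred_tissue or '.'}\t{top:.4f}\n"
            )
    summary["stages"]["express"] = {
        "size_factors": {k: round(float(v), 6) for k, v in matrix.size_factors.items()},
        "pseudocount": pseudo,
        "category_tally": {
            cat: sum(1 for s in spec_calls if s.category == cat)
            for cat in ("ubiquitous", "preferential", "specific", "below_detection")
        },
        "qpcr_normalizer_candidates": normalizers,
        "abundance_categories": {
            s.mirna_id: expr.categorize_abundance(
                float(matrix.normalized.loc[s.mirna_id].max())
            )
            for s in spec_calls
        },
    }

    # --- summary + truth comparison ------------------------------------
    summary["calls"] = summarize_calls(calls, matrix, config.detection_min)
    summary["truth_recovery"] = _score_against_truth(novel_calls, truth)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")

    manifest = {
        "config": dataclasses.asdict(config),
        "outputs": {
            p.relative_to(outdir).as_posix(): _sha256(p)
            for p in sorted(outdir.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")
    summary["manifest_sha256"] = hashlib.sha256(
        (outdir / "manifest.json").read_bytes()
    ).hexdigest()
    return summary


def _score_against_truth(novel_calls: list, truth: syn.TruthTable) -> dict:
    """Recall/precision of novel calls against planted truth at hairpin
    resolution: a call recovers a planted miRNA when its mature sequence is
    identical and one of its loci overlaps the planted precursor locus.

    Strand is deliberately not compared: a perfectly complementary stem is
    an exact inverted repeat, so the mature maps equally well antisense
    onto the other arm and the orientation of the hairpin is unidentifiable
    from exact-match placements alone."""

    def _overlaps(a, rec) -> bool:
        t = rec.locus
        return a.chrom == t.chrom and a.start < t.end and t.start < a.end

    matched_truth = set()
    matched_calls = 0
    for c in novel_calls:
        hit = False
        for rec in truth.records:
            if c.seq == rec.mature_seq and any(
                _overlaps(loc, rec) for loc in c.loci
            ):
                matched_truth.add(rec.id)
                hit = True
        matched_calls += int(hit)
    n_truth, n_calls = len(truth.records), len(novel_calls)
    return {
        "n_truth": n_truth,
        "n_called": n_calls,
        "true_positive": matched_calls,
        "recall": len(matched_truth) / n_truth if n_truth else None,
        "precision": matched_calls / n_calls if n_calls else None,
    }


def _write_candidate_table(candidates: list, path: Path) -> None:
    cols = [
        "chrom", "start", "end", "strand", "mature_seq", "mature_offset",
        "star_seq", "duplex_pairs", "len_diff", "shuffle_p",
        "dicer_consistency", "total_count", "star_evidence", "accepted",
    ] + [f"v_{k}" for k in disc.VERDICT_KEYS]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in candidates:
            row = [
                c.locus.chrom, c.locus.start, c.locus.end, c.locus.strand,
                c.mature_seq, c.mature_offset, c.star_seq or ".",
                c.duplex_pairs, c.len_diff if c.len_diff is not None else ".",
                f"{c.shuffle_p:.4f}" if c.shuffle_p is not None else ".",
                f"{c.dicer_consistency:.4f}" if c.dicer_consistency is not None else ".",
                c.total_count, int(c.star_evidence), int(c.accepted),
            ] + [
                "." if c.verdicts.get(k) is None else int(c.verdicts[k])
                for k in disc.VERDICT_KEYS
            ]
            fh.write("\t".join(str(x) for x in row) + "\n")


def _write_call_outputs(calls: list, outdir: Path) -> None:
    with open(outdir / "mature.bed", "w") as fh:
        for c in calls:
            for loc in c.loci:
                fh.write(
                    f"{loc.chrom}\t{loc.start}\t{loc.end}\t{c.id}\t{c.total}\t{loc.strand}\n"
                )
    with open(outdir / "mature.fa", "w") as fh:
        for c in calls:
            fh.write(f">{c.id}\n{c.seq}\n")
    with open(outdir / "precursors.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for c in calls:
            p = c.precursor
            if p is None:
                continue
            loc = p.locus
            fh.write(
                f"{loc.chrom}\tmirforge\tmiRNA_primary_transcript\t{loc.start + 1}\t"
                f"{loc.end}\t.\t{loc.strand}\t.\tID={c.id}.pre\n"
            )
            for kind, off, seq in (
                ("miRNA", p.mature_offset, p.mature_seq),
                ("miRNA_star", p.star_offset, p.star_seq),
            ):
                if off is None or seq is None:
                    continue
                if loc.strand == "+":
                    s, e = loc.start + off, loc.start + off + len(seq)
                else:
                    s, e = loc.end - off - len(seq), loc.end - off
                fh.write(
                    f"{loc.chrom}\tmirforge\t{kind}\t{s + 1}\t{e}\t.\t{loc.strand}\t.\t"
                    f"ID={c.id}.{kind};Parent={c.id}.pre\n"
                )
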