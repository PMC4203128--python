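#!/usr/bin/env python
"""Predict novel miRNAs from the genome-mapped tags via the hairpin
criteria checklist, cluster them into families, and compare against the
planted truth.

Reads results/study/{genome.fa,tags.tsv,truth.tsv}; writes
results/study/{candidates.tsv,mature.bed,mature.fa,precursors.gff3} and
results/discovery_summary.json.
"""

import json
import sys
from pathlib import Path

import pandas as pd
from Bio import SeqIO

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_config import RESULTS, STUDY, THRESHOLDS

from mirforge.discovery import cluster_families, discover_novel
from mirforge.preprocess import read_tag_table
from mirforge.pipeline import _write_call_outputs, _write_candidate_table


def main():
    genome = {
        r.id: str(r.seq).upper()
        for r in SeqIO.parse(str(STUDY / "genome.fa"), "fasta")
    }
    tags = read_tag_table(STUDY / "tags.tsv")
    calls, candidates = discover_novel(tags, genome, THRESHOLDS)
    families = cluster_families(calls, identity=THRESHOLDS.identity)
    _write_candidate_table(candidates, STUDY / "candidates.tsv")
    _write_call_outputs(calls, STUDY)

    truth = pd.read_csv(STUDY / "truth.tsv", sep="\t")
    truth_seqs = set(truth["mature_seq"])
    recovered = sum(1 for c in calls if c.seq in truth_seqs)
    mfe = [c.precursor.mfe for c in calls if c.precursor and c.precursor.mfe is not None]
    summary = {
        "tags_in": len(tags),
        "candidates_evaluated": len(candidates),
        "novel_accepted": len(calls),
        "planted": len(truth),
        "recovered": recovered,
        "n_families": len(families),
        "mean_mfe_kcal_mol": round(sum(mfe) / len(mfe), 2) if mfe else None,
        "mfe_below_minus20": sum(1 for m in mfe if m < -20),
    }
    with open(RESULTS / "discovery_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    print(
        f"{summary['candidates_evaluated']} candidate windows -> "
        f"{summary['novel_accepted']} accepted novel miRNAs; "
        f"{recovered}/{len(truth)} planted hairpins recovered"
    )
    print(
        f"families: {summary['n_families']}; mean precursor MFE "
        f"{summary['mean_mfe_kcal_mol']} kcal/mol, "
        f"{summary['mfe_below_minus20']}/{len(mfe)} below -20"
    )


if __name__ == "__main__":
    main()
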