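#!/usr/bin/env python
"""Normalize per-tissue miRNA counts (median-of-ratios), categorize
abundance, and call tissue-preferential/specific expression.

Reads results/study/{mature.fa,tags.tsv}; writes
results/study/{normalized.tsv,size_factors.tsv,specificity.tsv} and
results/expression_summary.json.
"""

import json
import sys
from pathlib import Path

from Bio import SeqIO

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_config import RESULTS, STUDY, SYNTH

from mirforge.discovery import MiRNACall
from mirforge.expression import (
    CountMatrix,
    categorize_abundance,
    estimate_size_factors,
    rank_tissue_preference,
)
from mirforge.preprocess import read_tag_table


def main():
    tags = read_tag_table(STUDY / "tags.tsv")
    calls = []
    for rec in SeqIO.parse(str(STUDY / "mature.fa"), "fasta"):
        seq = str(rec.seq)
        calls.append(
            MiRNACall(
                id=rec.id, seq=seq, class_="novel", family=".",
                loci=[], counts=dict(tags[seq].counts) if seq in tags else {},
            )
        )
    samples = list(SYNTH.tissues)
    m = CountMatrix.from_calls(calls, samples)
    m.size_factors = estimate_size_factors(m)
    spec_calls, normalizers = rank_tissue_preference(m)
    m.normalized.round(4).to_csv(STUDY / "normalized.tsv", sep="\t")
    m.size_factors.round(6).to_csv(STUDY / "size_factors.tsv", sep="\t")
    with open(STUDY / "specificity.tsv", "w") as fh:
        fh.write("mirna_id\tcategory\tpreferred_tissue\ttop_fraction\n")
        for s in spec_calls:
            top = max(s.fractions.values()) if s.fractions else 0.0
            fh.write(
                f"{s.mirna_id}\t{s.category}\t{s.preferred_tissue or '.'}\t{top:.4f}\n"
            )
    tally = {}
    for s in spec_calls:
        tally[s.category] = tally.get(s.category, 0) + 1
    abundance = {
        s.mirna_id: categorize_abundance(float(m.normalized.loc[s.mirna_id].max()))
        for s in spec_calls
    }
    summary = {
        "size_factors": {k: round(float(v), 6) for k, v in m.size_factors.items()},
        "category_tally": tally,
        "qpcr_normalizer_candidates": normalizers,
        "abundance_tally": {
            lab: sum(1 for v in abundance.values() if v == lab)
            for lab in sorted(set(abundance.values()))
        },
    }
    with open(RESULTS / "expression_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    print(f"size factors: {summary['size_factors']}")
    print(f"specificity: {tally}; qPCR normalizer candidates: {normalizers}")


if __name__ == "__main__":
    main()
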