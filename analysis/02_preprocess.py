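#!/usr/bin/env python
"""Quality-filter, adapter-trim and collapse each tissue library into
unique 18-30 nt tags with per-sample counts.

Reads results/study/reads/*.fastq; writes results/study/tags.tsv and
results/preprocess_stats.json.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_config import RESULTS, STUDY, SYNTH

from mirforge.preprocess import merge_tag_tables, preprocess_fastq, write_tag_table


def main():
    per_sample, stats = {}, {}
    for tissue in SYNTH.tissues:
        tags, st = preprocess_fastq(
            STUDY / "reads" / f"{tissue}.fastq", tissue, adapter=SYNTH.adapter_seq
        )
        per_sample[tissue] = tags
        stats[tissue] = st.as_dict()
        print(
            f"{tissue}: {st.raw_reads} reads -> {st.post_qc_reads} post-QC, "
            f"{st.unique_tags} unique tags "
            f"(sizes {min(st.size_histogram)}-{max(st.size_histogram)})"
        )
    merged = merge_tag_tables(per_sample)
    write_tag_table(merged, list(SYNTH.tissues), STUDY / "tags.tsv")
    with open(RESULTS / "preprocess_stats.json", "w") as fh:
        json.dump(stats, fh, indent=1, sort_keys=True)
    print(f"{len(merged)} merged unique tags -> {STUDY / 'tags.tsv'}")


if __name__ == "__main__":
    main()
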