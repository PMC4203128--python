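"""Shared configuration for the numbered analysis scripts.

The study conditions: a 100 kb synthetic genome carrying 20 planted miRNA
hairpins expressed across three tissues with zero read noise, processed
end-to-end by the mirforge pipeline. All scripts write under results/.
"""

from pathlib import Path

from mirforge.discovery import DiscoveryThresholds
from mirforge.synthetic import SyntheticConfig

SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"
STUDY = RESULTS / "study"

SYNTH = SyntheticConfig(seed=SEED * 3 + 1)  # same derivation as RunConfig
THRESHOLDS = DiscoveryThresholds(seed=(SEED * 3 + 2) & 0x7FFFFFFF)
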