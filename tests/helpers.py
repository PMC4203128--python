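"""Construction helpers shared by the discovery tests and the acceptance
suite: a compliant hairpin candidate plus the four rejection-injected
controls (short duplex, low read support, mature/star length delta 7,
bifurcated precursor)."""

from mirforge._seq import revcomp
from mirforge.discovery import (
    DiscoveryThresholds,
    GenomeLocus,
    LocusTag,
    PrecursorCandidate,
    evaluate_candidate,
    fold_candidate,
)
from mirforge.preprocess import UniqueTag
from mirforge.synthetic import build_hairpin_precursor

MATURE = "TGGACGTGATCGTAGCAGTTC"  # 21 nt
LOOP = "CAACAACA"


def evaluate_control(precursor: str, counts: int = 50, thresholds=None):
    """Wrap a hand-built precursor (mature at offset 0) as a candidate and
    run the criteria checklist with a single supporting tag."""
    cand = PrecursorCandidate(
        locus=GenomeLocus("ctrl", 1000, 1000 + len(precursor), "+"),
        seq=precursor,
        mature_seq=MATURE,
        mature_offset=0,
    )
    fold_candidate(cand, "energy")
    tags = [LocusTag(UniqueTag(MATURE, {"shoot": counts}), 0)]
    evaluate_candidate(cand, tags, thresholds or DiscoveryThresholds())
    return cand


def compliant_precursor() -> str:
    pre, _star = build_hairpin_precursor(MATURE, "5p", 8, 0.0, rng_seed=1)
    return pre


def duplex13_precursor() -> str:
    """Six central stem mismatches leave only 13 mature:star duplex pairs."""
    comp = list(revcomp(MATURE))
    for i in range(5, 11):
        comp[len(MATURE) - 1 - i] = MATURE[i]
    return MATURE + LOOP + "".join(comp) + "AC"


def len_delta7_precursor() -> str:
    """A 7-nt bulge in the complementary arm makes the star 7 nt longer
    than the mature while keeping >= 14 duplex pairs."""
    comp = revcomp(MATURE)
    return MATURE + LOOP + comp[:10] + "CAACAAC" + comp[10:] + "AC"


def bifurcated_precursor() -> str:
    """Two extra stem-loops between the arms: the mature-to-star span folds
    with more than one hairpin loop."""
    hp2 = "GGCGGC" + "AACAA" + "GCCGCC"
    hp3 = "GCCGG" + "ACAAA" + "CCGGC"
    return MATURE + "CAA" + hp2 + "AAC" + hp3 + "CAA" + revcomp(MATURE) + "AC"
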