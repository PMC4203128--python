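"""miRNA expression analysis: median-of-ratios normalization, abundance
categories, tissue-preferential/specific calls, and qPCR validation
(delta-delta-CT with cross-platform correlation).

Counts live in a :class:`CountMatrix` (pandas DataFrame of miRNA x sample
raw counts plus per-sample size factors). Size factors follow the
median-of-ratios scheme: for rows with positive counts in every sample,
factor_j = median_i( raw[i,j] / geometric_mean_i ).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "CountMatrix",
    "SpecificityCall",
    "QPCRTable",
    "estimate_size_factors",
    "categorize_abundance",
    "rank_tissue_preference",
    "delta_delta_ct",
    "correlate_platforms",
]

ABUNDANCE_LABELS = ("very_low", "low", "moderate", "high", "very_high")
DEFAULT_BREAKS = (10.0, 100.0, 1000.0, 10000.0)


@dataclass
class CountMatrix:
    """miRNA x sample raw counts with size factors."""

    raw: pd.DataFrame  # rows miRNA ids, columns sample labels, ints
    size_factors: pd.Series | None = None

    @property
    def normalized(self) -> pd.DataFrame:
        if self.size_factors is None:
            raise ValueError("size factors not estimated yet")
        return self.raw / self.size_factors

    @classmethod
    def from_calls(cls, calls: list, samples: list) -> "CountMatrix":
        data = {
            c.id: [c.counts.get(s, 0) for s in samples] for c in calls
        }
        raw = pd.DataFrame.from_dict(
            data, orient="index", columns=list(samples)
        ).astype(int)
        return cls(raw=raw)


@dataclass
class SpecificityCall:
    mirna_id: str
    fractions: dict  # tissue -> share of total normalized expression
    preferred_tissue: str | None
    category: str  # ubiquitous | preferential | specific | below_detection


@dataclass
class QPCRTable:
    """CT values keyed by (target, sample, replicate)."""

    ct: dict
    reference_gene: str = "U6"

    def __post_init__(self):
        if any(v <= 0 for v in self.ct.values()):
            raise ValueError("CT values must be positive")
        samples = {s for (_t, s, _r) in self.ct}
        ref_samples = {s for (t, s, _r) in self.ct if t == self.reference_gene}
        missing = samples - ref_samples
        if missing:
            raise ValueError(
                f"reference gene {self.reference_gene!r} missing in samples {sorted(missing)}"
            )

    def targets(self) -> list:
        return sorted({t for (t, _s, _r) in self.ct if t != self.reference_gene})

    def samples(self) -> list:
        return sorted({s for (_t, s, _r) in self.ct})

    def replicate_cts(self, target: str, sample: str) -> list:
        return [
            v for (t, s, _r), v in sorted(self.ct.items()) if t == target and s == sample
        ]


def estimate_size_factors(
    raw: pd.DataFrame | CountMatrix, pseudocount: float = 0.0
) -> pd.Series:
    """Median-of-ratios size factors.

    Rows containing a zero in any sample are excluded from the median
    (standard convention); with no all-positive row, a positive
    ``pseudocount`` must be supplied.
    """
    df = raw.raw if isinstance(raw, CountMatrix) else raw
    if df.shape[1] < 2:
        raise ValueError("need at least two samples")
    mat = df.to_numpy(dtype=float) + pseudocount
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no row with positive counts in all samples; pass pseudocount > 0"
        )
    sub = mat[positive]
    log_gm = np.log(sub).mean(axis=1)
    factors = np.exp(np.median(np.log(sub) - log_gm[:, None], axis=0))
    return pd.Series(factors, index=df.columns, name="size_factor")


def categorize_abundance(
    normalized: float, breaks: tuple = DEFAULT_BREAKS
) -> str:
    """Five-level abundance category by half-open binning on ``breaks``
    ([0, b1) -> very_low, [b1, b2) -> low, ..., [b4, inf) -> very_high)."""
    if normalized < 0:
        raise ValueError("normalized expression must be >= 0")
    if list(breaks) != sorted(breaks) or len(set(breaks)) != len(breaks):
        raise ValueError("breaks must be strictly ascending")
    if len(breaks) != len(ABUNDANCE_LABELS) - 1:
        raise ValueError("need exactly four break points for five categories")
    for label, b in zip(ABUNDANCE_LABELS, breaks):
        if normalized < b:
            return label
    return ABUNDANCE_LABELS[-1]


def rank_tissue_preference(
    matrix: CountMatrix,
    detection_min: float = 10.0,
    pref_ratio: float = 2.0,
    spec_frac: float = 0.90,
    n_normalizers: int = 5,
) -> tuple[list, list]:
    """Tissue-preference ranking of each miRNA on normalized expression.

    below_detection: below ``detection_min`` in every tissue. specific:
    top-tissue share >= ``spec_frac`` and every other tissue below
    ``detection_min``. preferential: top tissue >= ``pref_ratio`` x the
    second-highest. ubiquitous otherwise. Also returns the
    lowest-coefficient-of-variation ubiquitous miRNAs (candidate qPCR
    normalizers).
    """
    norm = matrix.normalized
    calls = []
    cv_pool = []
    for mid, row in norm.iterrows():
        vals = row.to_numpy(dtype=float)
        if (vals < detection_min).all():
            calls.append(
                SpecificityCall(
                    mirna_id=mid, fractions={}, preferred_tissue=None,
                    category="below_detection",
                )
            )
            continue
        total = vals.sum()
        fractions = {t: v / total for t, v in row.items()}
        order = np.argsort(vals)[::-1]
        top, second = order[0], order[1]
        preferred = norm.columns[top]
        others_below = all(
            vals[i] < detection_min for i in range(len(vals)) if i != top
        )
        if fractions[preferred] >= spec_frac and others_below:
            category = "specific"
        elif vals[top] >= pref_ratio * vals[second]:
            category = "preferential"
        else:
            category = "ubiquitous"
        if category == "ubiquitous":
            mean = vals.mean()
            cv_pool.append((vals.std(ddof=0) / mean if mean > 0 else np.inf, mid))
        calls.append(
            SpecificityCall(
                mirna_id=mid,
                fractions=fractions,
                preferred_tissue=preferred,
                category=category,
            )
        )
    normalizers = [mid for _cv, mid in sorted(cv_pool)[:n_normalizers]]
    return calls, normalizers


def delta_delta_ct(table: QPCRTable, calibrator_sample: str) -> pd.DataFrame:
    """Livak delta-delta-CT relative quantification.

    For each (target, sample): dCT = mean CT_target - mean CT_reference;
    ddCT = dCT_sample - dCT_calibrator; RQ = 2^-ddCT. Replicate SD of dCT
    is taken over paired technical replicates and propagated to RQ by the
    delta method (rq_sd = RQ * ln2 * sd_dct).
    """
    samples = table.samples()
    if calibrator_sample not in samples:
        raise ValueError(f"calibrator sample {calibrator_sample!r} not measured")
    rows = []
    dct: dict[tuple, tuple] = {}
    for target in table.targets():
        for sample in samples:
            t_cts = table.replicate_cts(target, sample)
            r_cts = table.replicate_cts(table.reference_gene, sample)
            if not t_cts:
                continue
            d = float(np.mean(t_cts) - np.mean(r_cts))
            if len(t_cts) == len(r_cts) and len(t_cts) > 1:
                sd = float(np.std(np.array(t_cts) - np.array(r_cts), ddof=1))
            else:
                sd = 0.0
            dct[(target, sample)] = (d, sd)
    for (target, sample), (d, sd) in sorted(dct.items()):
        cal = dct.get((target, calibrator_sample))
        if cal is None:
            raise ValueError(
                f"calibrator sample {calibrator_sample!r} missing for {target!r}"
            )
        ddct = d - cal[0]
        rq = 2.0 ** (-ddct)
        rows.append(
            {
                "target": target,
                "sample": sample,
                "delta_ct": d,
                "delta_ct_sd": sd,
                "ddct": ddct,
                "rq": rq,
                "rq_sd": rq * math.log(2) * sd,
            }
        )
    return pd.DataFrame(rows)


def correlate_platforms(
    seq_normalized, qpcr_rq, pseudocount: float = 1.0
) -> tuple[float, int]:
    """Pearson correlation between sequencing and qPCR expression on the
    log2 scale over matched (miRNA, sample) pairs.

    Returns (r, n_pairs). Sequencing values get ``pseudocount`` before the
    log; RQ values are strictly positive already.
    """
    x = np.asarray(seq_normalized, dtype=float)
    y = np.asarray(qpcr_rq, dtype=float)
    if x.shape != y.shape:
        raise ValueError("platform vectors must be matched pairwise")
    if x.size < 3:
        raise ValueError("need at least 3 matched pairs")
    r, _p = sstats.pearsonr(np.log2(x + pseudocount), np.log2(y))
    return float(r), int(x.size)
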