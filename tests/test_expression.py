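"""Normalization, abundance categories, specificity ranking and qPCR tests.

The median-of-ratios implementation is cross-checked against pydeseq2's
deseq2_norm as an independent oracle.
"""

import numpy as np
import pandas as pd
import pytest

from mirforge.expression import (
    CountMatrix,
    QPCRTable,
    categorize_abundance,
    correlate_platforms,
    delta_delta_ct,
    estimate_size_factors,
    rank_tissue_preference,
)


class TestSizeFactors:
    def test_hand_derived_example(self):
        raw = pd.DataFrame({"A": [10, 20, 30], "B": [20, 40, 60]})
        sf = estimate_size_factors(raw)
        assert sf["A"] == pytest.approx(0.70711, abs=1e-5)
        assert sf["B"] == pytest.approx(1.41421, abs=1e-5)
        norm = raw / sf
        assert np.allclose(norm["A"], norm["B"])

    def test_identical_samples_unit_factors(self):
        raw = pd.DataFrame({"A": [5, 9, 13], "B": [5, 9, 13], "C": [5, 9, 13]})
        assert np.allclose(estimate_size_factors(raw), 1.0)

    def test_row_permutation_invariant(self, rng):
        raw = pd.DataFrame(rng.integers(1, 200, size=(20, 4)))
        perm = raw.sample(frac=1.0, random_state=3)
        assert np.allclose(estimate_size_factors(raw), estimate_size_factors(perm))

    def test_exact_scaling_recovered(self):
        a = np.array([11, 40, 97, 250, 3])
        raw = pd.DataFrame({"A": a, "B": 4 * a})
        sf = estimate_size_factors(raw)
        assert sf["B"] / sf["A"] == pytest.approx(4.0, abs=1e-9)

    def test_median_ratio_unity_after_normalization(self, rng):
        # exact for two samples with an odd row count: the median commutes
        # with the monotone map x -> sqrt(x) linking pairwise ratios to the
        # per-sample gm ratios
        raw = pd.DataFrame(rng.integers(1, 500, size=(31, 2)), columns=["A", "B"])
        norm = raw / estimate_size_factors(raw)
        assert np.median(norm["A"] / norm["B"]) == pytest.approx(1.0, abs=1e-9)

    def test_matches_pydeseq2(self, rng):
        from pydeseq2.preprocessing import deseq2_norm

        counts = pd.DataFrame(rng.integers(1, 500, size=(40, 6)))  # genes x samples
        ours = estimate_size_factors(counts)
        _normed, theirs = deseq2_norm(counts.T)  # pydeseq2 wants samples x genes
        assert np.allclose(ours.to_numpy(), np.asarray(theirs))

    def test_all_zero_rows_require_pseudocount(self):
        raw = pd.DataFrame({"A": [0, 5], "B": [3, 0]})
        with pytest.raises(ValueError):
            estimate_size_factors(raw)
        sf = estimate_size_factors(raw, pseudocount=1.0)
        assert (sf > 0).all()


class TestAbundance:
    @pytest.mark.parametrize(
        "value,label",
        [
            (5, "very_low"),
            (10, "low"),  # boundary is half-open
            (50, "low"),
            (500, "moderate"),
            (5000, "high"),
            (50000, "very_high"),
        ],
    )
    def test_binning(self, value, label):
        assert categorize_abundance(value) == label

    def test_monotone(self, rng):
        order = ["very_low", "low", "moderate", "high", "very_high"]
        vals = sorted(rng.uniform(0, 20000, size=50))
        cats = [order.index(categorize_abundance(v)) for v in vals]
        assert cats == sorted(cats)

    def test_bad_breaks_rejected(self):
        with pytest.raises(ValueError):
            categorize_abundance(5, breaks=(10, 5, 100, 1000))


def _matrix(rows, samples):
    raw = pd.DataFrame(rows, columns=samples).T.T
    m = CountMatrix(raw=raw)
    m.size_factors = pd.Series(1.0, index=samples)
    return m


class TestSpecificity:
    SAMPLES = list("ABCDEFG")

    def test_single_tissue_is_specific(self):
        m = _matrix({"x": [100, 0, 0, 0, 0, 0, 0]}, self.SAMPLES)
        m.raw = pd.DataFrame([[100, 0, 0, 0, 0, 0, 0]], index=["x"], columns=self.SAMPLES)
        calls, _ = rank_tissue_preference(m)
        assert calls[0].category == "specific"
        assert calls[0].fractions["A"] == 1.0

    def test_uniform_is_ubiquitous(self):
        m = CountMatrix(
            raw=pd.DataFrame([[10] * 7], index=["x"], columns=self.SAMPLES),
            size_factors=pd.Series(1.0, index=self.SAMPLES),
        )
        calls, normalizers = rank_tissue_preference(m)
        assert calls[0].category == "ubiquitous"
        assert normalizers == ["x"]

    def test_preferential_but_not_specific(self):
        m = CountMatrix(
            raw=pd.DataFrame(
                [[80, 10, 5, 5, 0, 0, 0]], index=["x"], columns=self.SAMPLES
            ),
            size_factors=pd.Series(1.0, index=self.SAMPLES),
        )
        calls, _ = rank_tissue_preference(m)
        assert calls[0].category == "preferential"
        assert calls[0].preferred_tissue == "A"

    def test_below_detection(self):
        m = CountMatrix(
            raw=pd.DataFrame([[3] * 7], index=["x"], columns=self.SAMPLES),
            size_factors=pd.Series(1.0, index=self.SAMPLES),
        )
        calls, _ = rank_tissue_preference(m)
        assert calls[0].category == "below_detection"


class TestDeltaDeltaCT:
    def _table(self):
        return QPCRTable(
            ct={
                ("miR-x", "A", 1): 25.0,
                ("U6", "A", 1): 20.0,
                ("miR-x", "B", 1): 24.0,
                ("U6", "B", 1): 20.0,
            }
        )

    def test_calibrator_rq_is_one(self):
        df = delta_delta_ct(self._table(), "A")
        row = df[df["sample"] == "A"].iloc[0]
        assert row["rq"] == pytest.approx(1.0)

    def test_worked_example_rq_two(self):
        df = delta_delta_ct(self._table(), "A")
        row = df[df["sample"] == "B"].iloc[0]
        assert row["rq"] == pytest.approx(2.0)

    def test_powers_of_two(self):
        # ddCT = -3 -> RQ = 8
        t = QPCRTable(
            ct={
                ("m", "A", 1): 25.0,
                ("U6", "A", 1): 20.0,
                ("m", "B", 1): 22.0,
                ("U6", "B", 1): 20.0,
            }
        )
        df = delta_delta_ct(t, "A")
        assert df[df["sample"] == "B"].iloc[0]["rq"] == pytest.approx(8.0)

    def test_replicate_sd_from_paired_replicates(self):
        t = QPCRTable(
            ct={
                ("m", "A", 1): 25.0,
                ("m", "A", 2): 25.4,
                ("U6", "A", 1): 20.0,
                ("U6", "A", 2): 20.0,
            }
        )
        df = delta_delta_ct(t, "A")
        assert df.iloc[0]["delta_ct_sd"] == pytest.approx(
            np.std([5.0, 5.4], ddof=1)
        )

    def test_missing_calibrator_rejected(self):
        with pytest.raises(ValueError):
            delta_delta_ct(self._table(), "Z")

    def test_nonpositive_ct_rejected(self):
        with pytest.raises(ValueError):
            QPCRTable(ct={("m", "A", 1): -1.0, ("U6", "A", 1): 20.0})

    def test_reference_required_everywhere(self):
        with pytest.raises(ValueError):
            QPCRTable(ct={("m", "A", 1): 22.0, ("m", "B", 1): 23.0, ("U6", "A", 1): 20.0})


class TestCorrelation:
    def test_proportional_log_vectors(self):
        seq = np.array([1.0, 3.0, 7.0, 15.0])
        rq = (seq + 1.0) ** 1.7  # log-linear in log2(seq + 1)
        r, n = correlate_platforms(seq, rq)
        assert r == pytest.approx(1.0) and n == 4

    def test_antilinear(self):
        seq = np.array([1.0, 3.0, 7.0, 15.0])
        rq = (seq + 1.0) ** -2.0
        r, _ = correlate_platforms(seq, rq)
        assert r == pytest.approx(-1.0)

    def test_hand_pearson(self):
        # log2(rq) exactly double log2(seq+1): perfectly linear, r = 1
        seq = np.array([1.0, 3.0, 7.0])
        rq = np.array([4.0, 16.0, 64.0])
        r, _ = correlate_platforms(seq, rq)
        assert r == pytest.approx(1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            correlate_platforms([1.0, 2.0], [1.0, 2.0])
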