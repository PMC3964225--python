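"""Aggregation, error-factor and local-FDR behavior of the quantify stage."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from itraqpipe.io_formats import PeptideRecord
from itraqpipe import quantify as q


def peptides(ratios, sample="C1", confidence=0.99, accession="P1",
             decoy=False):
    return [PeptideRecord(accession, f"PEP{i}", confidence, decoy,
                          {sample: r})
            for i, r in enumerate(ratios)]


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

class TestAggregation:
    def test_geometric_mean_symmetry(self):
        quant = q.aggregate_protein_ratio(peptides([0.5, 2.0]))
        assert quant.sample_ratios["C1"] == pytest.approx(1.0)

    def test_geometric_mean_powers_of_two(self):
        quant = q.aggregate_protein_ratio(peptides([1.0, 2.0, 4.0]))
        assert quant.sample_ratios["C1"] == pytest.approx(2.0)
        assert quant.n_peptides["C1"] == 3

    def test_identical_peptides_have_zero_ef(self):
        quant = q.aggregate_protein_ratio(peptides([1.7, 1.7, 1.7]))
        assert quant.sample_ratios["C1"] == pytest.approx(1.7)
        assert quant.ef_percent["C1"] == pytest.approx(0.0)

    def test_single_peptide_has_undefined_ef(self):
        quant = q.aggregate_protein_ratio(peptides([1.7]))
        assert math.isinf(quant.ef_percent["C1"])

    def test_low_confidence_and_decoys_do_not_quantify(self):
        recs = peptides([2.0, 2.0, 2.0], confidence=0.5) \
            + peptides([9.0], confidence=0.99, decoy=True)
        quant = q.aggregate_protein_ratio(recs)
        assert quant.sample_ratios == {}
        assert not quant.is_decoy  # some records are targets

    def test_pure_decoy_protein_is_flagged(self):
        quant = q.aggregate_protein_ratio(
            peptides([1.0, 1.1], accession="REV_P1", decoy=True))
        assert quant.is_decoy and quant.sample_ratios == {}

    def test_mixed_accessions_rejected(self):
        recs = peptides([1.0]) + peptides([1.0], accession="P2")
        with pytest.raises(ValueError, match="mixed accessions"):
            q.aggregate_protein_ratio(recs)

    def test_matches_log_space_oracle_on_random_inputs(self, rng):
        """Geometric mean and t-based EF agree with a brute-force oracle."""
        from scipy import stats as sps
        for _ in range(50):
            n = int(rng.integers(2, 9))
            ratios = rng.lognormal(0.2, 0.5, size=n).tolist()
            quant = q.aggregate_protein_ratio(peptides(ratios))
            logs = [math.log10(r) for r in ratios]
            mean = sum(logs) / n
            assert quant.sample_ratios["C1"] == pytest.approx(10 ** mean)
            sd = math.sqrt(sum((x - mean) ** 2 for x in logs) / (n - 1))
            half = sps.t.ppf(0.975, n - 1) * sd / math.sqrt(n)
            assert quant.ef_percent["C1"] == pytest.approx(
                (10 ** half - 1) * 100)

    @given(st.floats(0.05, 20.0))
    def test_scale_consistency(self, c):
        """Scaling every peptide ratio by c scales the protein ratio by c
        and leaves EF unchanged."""
        base = [0.8, 1.3, 2.1]
        q0 = q.aggregate_protein_ratio(peptides(base))
        q1 = q.aggregate_protein_ratio(peptides([c * r for r in base]))
        assert q1.sample_ratios["C1"] == pytest.approx(
            c * q0.sample_ratios["C1"])
        assert q1.ef_percent["C1"] == pytest.approx(q0.ef_percent["C1"])


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def make_quant(acc, ratio=1.0, n=5, ef=5.0, samples=("C1",)):
    return q.ProteinQuant(acc,
                          {s: ratio for s in samples},
                          {s: n for s in samples},
                          {s: ef for s in samples})


class TestFilter:
    def test_below_minimum_peptides_dropped(self):
        quants = [make_quant("P1", n=2), make_quant("P2", n=3)]
        kept = q.filter_quantified(quants, keep_fraction=1.0)
        assert [k.accession for k in kept] == ["P2"]

    def test_floor_retention_can_empty_a_single_protein_list(self):
        # floor(0.95 * 1) == 0: percentile retention is a hard floor
        assert q.filter_quantified([make_quant("P1")]) == []

    def test_percentile_retention_keeps_95_of_100(self, rng):
        quants = [make_quant(f"P{i}", ef=float(rng.uniform(0, 10)))
                  for i in range(100)]
        assert len(q.filter_quantified(quants)) == 95

    def test_equal_ef_tie_break_is_input_order(self):
        quants = [make_quant(f"P{i}", ef=3.0) for i in range(100)]
        kept = q.filter_quantified(quants)
        assert [k.accession for k in kept] == [f"P{i}" for i in range(95)]

    def test_high_ef_sample_ratio_removed(self):
        quant = q.ProteinQuant("P1", {"C1": 2.0, "C2": 2.0},
                               {"C1": 5, "C2": 5},
                               {"C1": 3.0, "C2": 40.0})
        kept = q.filter_quantified([quant], keep_fraction=1.0)
        assert set(kept[0].sample_ratios) == {"C1"}

    def test_never_increases_count_and_identity_settings(self):
        quants = [make_quant(f"P{i}", n=3 + i, ef=float(i)) for i in range(10)]
        kept = q.filter_quantified(quants, min_peptides=3,
                                   max_ef_percent=math.inf, keep_fraction=1.0)
        assert [k.accession for k in kept] == [x.accession for x in quants]

    @pytest.mark.parametrize("kf", [0.0, -0.1, 1.5])
    def test_bad_keep_fraction_rejected(self, kf):
        with pytest.raises(ValueError):
            q.filter_quantified([make_quant("P1")], keep_fraction=kf)


# ---------------------------------------------------------------------------
# local FDR
# ---------------------------------------------------------------------------

def oracle_local_fdr(entries, window):
    """Independent oracle: explicit rank windows + sklearn isotonic fit."""
    from sklearn.isotonic import isotonic_regression
    n = len(entries)
    order = sorted(range(n), key=lambda i: -entries[i][0])
    decoy = [entries[i][1] for i in order]
    half = window // 2
    raw, pos = [], []
    for i in range(n):
        if decoy[i]:
            continue
        lo = max(0, i - half)
        hi = min(n, lo + window)
        lo = max(0, hi - window)
        d = sum(decoy[lo:hi])
        t = (hi - lo) - d
        raw.append(min(1.0, d / t))
        pos.append(i)
    iso = isotonic_regression(raw, increasing=True)
    out = [1.0] * n
    for p, v in zip(pos, iso):
        out[p] = float(min(1.0, v))
    result = [1.0] * n
    for rank, i in enumerate(order):
        result[i] = out[rank]
    return result


class TestLocalFdr:
    def test_no_decoys_gives_zero(self):
        entries = [(float(s), False) for s in range(10)]
        assert q.estimate_local_fdr(entries, window=4) == [0.0] * 10

    def test_equal_scores_alternating_is_one(self):
        entries = [(5.0, i % 2 == 1) for i in range(10)]
        lfdr = q.estimate_local_fdr(entries, window=4)
        targets = [v for v, (_, d) in zip(lfdr, entries) if not d]
        assert targets == [1.0] * 5

    def test_decoys_always_get_one(self):
        entries = [(9.0, False), (8.0, True), (7.0, False), (1.0, True)]
        lfdr = q.estimate_local_fdr(entries, window=2)
        assert lfdr[1] == 1.0 and lfdr[3] == 1.0

    def test_matches_brute_force_window_oracle(self):
        """High-score block then interleaved target/decoy tail."""
        entries = [(100.0 - i, False) for i in range(20)]
        entries += [(20.0 - i, i % 2 == 1) for i in range(10)]
        got = q.estimate_local_fdr(entries, window=10)
        expected = oracle_local_fdr(entries, window=10)
        assert got == pytest.approx(expected)

    def test_matches_oracle_on_random_lists(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 60))
            entries = [(float(rng.normal(3, 2)), bool(rng.random() < 0.3))
                       for _ in range(n)]
            if all(d for _, d in entries):
                entries[0] = (entries[0][0], False)
            w = int(rng.integers(1, 15))
            assert q.estimate_local_fdr(entries, w) == pytest.approx(
                oracle_local_fdr(entries, w))

    def test_monotone_non_decreasing_with_decreasing_score(self, rng):
        entries = [(float(rng.normal(3, 2)), bool(rng.random() < 0.4))
                   for _ in range(200)]
        entries.append((99.0, False))
        lfdr = q.estimate_local_fdr(entries, window=20)
        ranked = sorted(zip(entries, lfdr), key=lambda e: -e[0][0])
        targets = [v for (s, d), v in ranked if not d]
        assert all(0.0 <= v <= 1.0 for v in targets)
        assert all(a <= b + 1e-12 for a, b in zip(targets, targets[1:]))

    def test_window_below_one_rejected(self):
        with pytest.raises(ValueError):
            q.estimate_local_fdr([(1.0, False)], window=0)


# ---------------------------------------------------------------------------
# merging sets
# ---------------------------------------------------------------------------

class TestMerge:
    def test_union_of_accessions_across_sets(self):
        s1 = [make_quant("P1", ratio=2.0, samples=("C1", "N1"))]
        s2 = [make_quant("P1", ratio=0.5, samples=("C2", "N2")),
              make_quant("P2", samples=("C2",))]
        m = q.merge_itraq_sets([("a", s1), ("b", s2)])
        assert m.shape == (2, 4)
        assert m.ratio("P1", "C1") == pytest.approx(2.0)
        assert m.ratio("P1", "C2") == pytest.approx(0.5)
        assert math.isnan(m.ratio("P2", "N1"))

    def test_reverse_accessions_removed(self):
        quants = [make_quant("REV_P1"), make_quant("P2")]
        m = q.merge_itraq_sets([("a", quants)])
        assert m.protein_ids == ["P2"]

    def test_local_fdr_above_threshold_removed(self):
        ok = make_quant("P1")
        bad = make_quant("P2")
        bad.local_fdr = 0.06
        m = q.merge_itraq_sets([("a", [ok, bad])])
        assert m.protein_ids == ["P1"]

    def test_duplicate_sample_across_sets_is_error(self):
        s1 = [make_quant("P1", samples=("C1",))]
        s2 = [make_quant("P2", samples=("C1",))]
        with pytest.raises(ValueError, match="sample 'C1'"):
            q.merge_itraq_sets([("a", s1), ("b", s2)])


def test_median_aggregated_ratio_recovers_true_fold(rng):
    """Fold-2 proteins measured with 20% CV peptide noise aggregate to
    within 10% of truth at the cohort median."""
    sigma = math.sqrt(math.log(1 + 0.2 ** 2))
    medians = []
    for _ in range(200):
        n = 1 + int(rng.poisson(4))
        ratios = (2.0 * np.exp(rng.normal(0, sigma, n))).tolist()
        quant = q.aggregate_protein_ratio(peptides(ratios))
        medians.append(quant.sample_ratios["C1"])
    assert np.median(medians) == pytest.approx(2.0, rel=0.10)
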