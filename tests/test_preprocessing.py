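import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scakit.msa_io import MSA
from scakit.preprocessing import (
    PreprocessError,
    PreprocessParams,
    compute_weights,
    filter_sequences,
    fractional_identity,
    preprocess,
    resample_sequences,
    truncate_positions,
    truncate_weighted_gapped_positions,
    weighted_gap_frequency,
)

ALPHABET = "ACDEFGHIKLMNPQRSTVWY-"


def random_msa(rng, m, length, gap_p=0.1):
    rows = []
    for _ in range(m):
        codes = rng.integers(0, 20, size=length)
        gaps = rng.random(length) < gap_p
        rows.append(
            "".join("-" if g else ALPHABET[c] for c, g in zip(codes, gaps))
        )
    return MSA(ids=tuple(f"s{i}" for i in range(m)), rows=tuple(rows))


class TestFractionalIdentity:
    def test_self_identity(self):
        assert fractional_identity("ACDE", "ACDE") == 1.0

    def test_three_quarters(self):
        assert fractional_identity("ACDE", "ACDF") == 0.75

    def test_gap_gap_not_a_match(self):
        # matches at A and D only; denominator is the full length 4
        assert fractional_identity("A-DE", "A-DF") == 0.5

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            fractional_identity("AC", "ACD")

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_bruteforce_scan(self, seed):
        rng = np.random.default_rng(seed)
        r, s = (
            "".join(rng.choice(list(ALPHABET), size=12)) for _ in range(2)
        )
        expected = (
            sum(1 for a, b in zip(r, s) if a == b and a != "-") / 12
        )
        assert fractional_identity(r, s) == pytest.approx(expected)


class TestTruncatePositions:
    def test_reference_mode(self):
        msa = MSA(ids=("r", "o"), rows=("A-C", "DEF"))
        out, kept = truncate_positions(msa, reference_id="r")
        assert kept == [0, 2]
        assert out.rows == ("AC", "DF")

    def test_cutoff_mode_removes_half_gapped(self):
        msa = MSA(ids=("a", "b"), rows=("A-", "AC"))
        out, kept = truncate_positions(msa, gap_cutoff=0.4)
        assert kept == [0]

    def test_matches_per_column_count_oracle(self):
        rng = np.random.default_rng(7)
        msa = random_msa(rng, 10, 5, gap_p=0.35)
        _, kept = truncate_positions(msa, gap_cutoff=0.4)
        for j in range(5):
            n_gaps = sum(row[j] == "-" for row in msa.rows)
            assert (j in kept) == (n_gaps / 10 <= 0.4)

    def test_all_removed_raises(self):
        msa = MSA(ids=("a", "b"), rows=("--", "--"))
        with pytest.raises(PreprocessError):
            truncate_positions(msa, gap_cutoff=0.4)


class TestFilterSequences:
    def test_gappy_sequence_removed(self):
        rows = ("AAAAAAA---", "AAAAAAAAAA", "AAAAAAAAAC")
        msa = MSA(ids=("a", "b", "c"), rows=rows)
        out, removed = filter_sequences(msa, seq_gap_cutoff=0.2)
        assert removed == ["a"]

    def test_low_identity_to_reference_removed(self):
        ref = "A" * 100
        low = "A" * 19 + "C" * 81  # identity 0.19
        ok = "A" * 25 + "C" * 75
        msa = MSA(ids=("r", "x", "y"), rows=(ref, low, ok))
        out, removed = filter_sequences(
            msa, seq_gap_cutoff=1.0, reference_id="r", min_ref_identity=0.2
        )
        assert removed == ["x"]

    def test_matches_bruteforce_rule_application(self):
        # sequences derived from the reference with graded divergence/gaps
        rng = np.random.default_rng(3)
        ref = "".join(rng.choice(list(ALPHABET[:-1]), size=10))
        rows = [ref]
        for mut_rate, n_gaps in [(0.1, 0), (0.5, 1), (0.9, 0), (0.2, 3), (0.7, 2)]:
            row = list(ref)
            for i in range(10):
                if rng.random() < mut_rate:
                    row[i] = ALPHABET[rng.integers(0, 20)]
            gap_at = rng.choice(10, size=n_gaps, replace=False)
            for g in gap_at:
                row[g] = "-"
            rows.append("".join(row))
        msa = MSA(ids=tuple(f"s{i}" for i in range(6)), rows=tuple(rows))
        out, removed = filter_sequences(
            msa, seq_gap_cutoff=0.2, reference_id="s0", min_ref_identity=0.2
        )
        survivors = []
        for rid, row in zip(msa.ids, msa.rows):
            gap_ok = row.count("-") / 10 <= 0.2
            ident = sum(
                1 for a, b in zip(msa.rows[0], row) if a == b and a != "-"
            ) / 10
            if rid == "s0" or (gap_ok and ident >= 0.2):
                survivors.append(rid)
        assert list(out.ids) == survivors

    def test_too_few_survivors_raises(self):
        msa = MSA(ids=("a", "b"), rows=("A---", "C---"))
        with pytest.raises(PreprocessError):
            filter_sequences(msa, seq_gap_cutoff=0.2)


class TestComputeWeights:
    def test_identical_sequences(self):
        msa = MSA(ids=("a", "b", "c"), rows=("ACDE",) * 3)
        w = compute_weights(msa, delta=0.8)
        assert np.allclose(w.w, 1 / 3)
        assert w.m_eff == pytest.approx(1.0)

    def test_mixed_neighborhoods(self):
        # s1 == s2; s3 and s4 unrelated to everything
        msa = MSA(
            ids=("s1", "s2", "s3", "s4"),
            rows=("AAAAA", "AAAAA", "CCCCC", "DDDDD"),
        )
        w = compute_weights(msa, delta=0.8)
        assert np.allclose(w.w, [0.5, 0.5, 1.0, 1.0])
        assert w.m_eff == pytest.approx(3.0)

    def test_single_sequence(self):
        msa = MSA(ids=("a",), rows=("ACDE",))
        w = compute_weights(msa, delta=0.8)
        assert w.w.tolist() == [1.0]

    def test_matches_bruteforce_pairwise_matrix(self):
        rng = np.random.default_rng(11)
        msa = random_msa(rng, 8, 12, gap_p=0.0)
        w = compute_weights(msa, delta=0.5)
        for s, row_s in enumerate(msa.rows):
            n = sum(
                1
                for row_r in msa.rows
                if fractional_identity(row_r, row_s) > 0.5
            )
            assert w.w[s] == pytest.approx(1 / n)


class TestWeightedGapTruncation:
    def test_all_gap_column_removed(self):
        msa = MSA(ids=("a", "b"), rows=("A-", "C-"))
        w = compute_weights(msa, delta=0.8)
        out, kept = truncate_weighted_gapped_positions(msa, w, gamma_pos=0.5)
        assert kept == [0]

    def test_hand_evaluated_weighted_fraction(self):
        # two duplicate pairs -> weights 1/2 each, M_eff = 2; one gap carried
        # by one member of the first pair: f0 = (1/2) / 2 = 0.25
        a1 = "AAAAAAAAA-"
        a2 = "AAAAAAAAAA"
        b = "CCCCCCCCCC"
        msa = MSA(ids=("a1", "a2", "b1", "b2"), rows=(a1, a2, b, b[:-1] + "C"))
        w = compute_weights(msa, delta=0.8)
        assert w.m_eff == pytest.approx(2.0)
        f0 = weighted_gap_frequency(msa, w)
        assert f0[-1] == pytest.approx(0.25)
        _, kept_tight = truncate_weighted_gapped_positions(msa, w, gamma_pos=0.2)
        assert 9 not in kept_tight
        _, kept_loose = truncate_weighted_gapped_positions(msa, w, gamma_pos=0.3)
        assert 9 in kept_loose

    def test_gap_free_untouched(self):
        msa = MSA(ids=("a", "b"), rows=("ACDE", "ACDF"))
        w = compute_weights(msa, delta=0.8)
        _, kept = truncate_weighted_gapped_positions(msa, w, gamma_pos=0.2)
        assert kept == [0, 1, 2, 3]


class TestResample:
    def test_noop_when_target_reaches_m(self):
        rng = np.random.default_rng(0)
        msa = random_msa(rng, 5, 8, gap_p=0.0)
        w = compute_weights(msa, delta=0.8)  # all distinct -> M_eff = 5
        out, idx = resample_sequences(msa, w, factor=1.5, seed=1)
        assert out is msa

    def test_uniform_weights_give_requested_size(self):
        msa = MSA(ids=tuple(f"s{i}" for i in range(10)), rows=("ACDEFGHIKL",) * 1 + tuple(
            "ACDEFGHIK" + c for c in "MNPQRSTVW"
        ))
        w = compute_weights(msa, delta=0.95)
        out, idx = resample_sequences(msa, w, factor=0.0 + 5 / w.m_eff, seed=3)
        assert out.M == 5

    def test_cluster_proportions_match_sampling_law(self):
        # 90/10 split of exact duplicates; oracle re-implements the stated
        # law (sequential weighted draws without replacement) independently.
        rows = tuple(["A" * 10] * 90 + ["C" * 10] * 10)
        msa = MSA(ids=tuple(f"s{i}" for i in range(100)), rows=rows)
        w = compute_weights(msa, delta=0.8)
        target = round(1.5 * w.m_eff)
        counts = []
        for seed in range(1000):
            out, idx = resample_sequences(msa, w, factor=1.5, seed=seed)
            counts.append(sum(1 for i in idx if i < 90))
        counts = np.array(counts)

        oracle_counts = []
        rng = np.random.default_rng(12345)
        for _ in range(4000):
            probs = w.w.copy()
            picked = []
            for _ in range(target):
                c = rng.choice(100, p=probs / probs.sum())
                picked.append(c)
                probs[c] = 0.0
            oracle_counts.append(sum(1 for i in picked if i < 90))
        oracle_counts = np.array(oracle_counts)
        se = np.sqrt(
            oracle_counts.var(ddof=1) / len(counts)
            + oracle_counts.var(ddof=1) / len(oracle_counts)
        )
        assert abs(counts.mean() - oracle_counts.mean()) <= 3 * max(se, 1e-9)


class TestPreprocessPipeline:
    def test_permissive_params_identity(self):
        rng = np.random.default_rng(5)
        msa = random_msa(rng, 6, 10, gap_p=0.05)
        params = PreprocessParams(
            pos_gap_cutoff=1.0,
            seq_gap_cutoff=1.0,
            min_ref_identity=0.0,
            weighted_pos_gap_cutoff=1.0,
        )
        out = preprocess(msa, params)
        assert out.msa.rows == msa.rows

    def test_toy_manual_trace(self):
        # 8 sequences x 6 columns: column 5 heavily gapped, sequence g gappy,
        # sequences a1/a2 duplicated
        rows = (
            "ACDEF-",
            "ACDEF-",
            "ACDEG-",
            "ACDHG-",
            "ACIHGA",
            "CCIHG-",
            "AC---A",
            "ACDEFA",
        )
        msa = MSA(ids=tuple("abcdefgh"), rows=rows)
        out = preprocess(msa, PreprocessParams())
        # column 5 has 6/8 = 0.75 gaps -> removed in step 1; sequence g then
        # has 3/5 gaps -> removed in step 2; no further weighted truncation
        assert out.msa.L == 5
        assert "g" not in out.msa.ids
        assert out.msa.M == 7
        steps = [s for s, _, _ in out.provenance]
        assert steps == [
            "truncate_positions",
            "filter_sequences",
            "truncate_weighted_gapped_positions",
        ]

    def test_determinism(self):
        rng = np.random.default_rng(9)
        msa = random_msa(rng, 30, 12, gap_p=0.1)
        params = PreprocessParams(resample=True, resample_factor=1.0, seed=4)
        a = preprocess(msa, params)
        b = preprocess(msa, params)
        assert a.msa == b.msa
        assert np.array_equal(a.weights.w, b.weights.w)


class TestProperties:
    def test_m_eff_invariant_under_duplication(self):
        rng = np.random.default_rng(2)
        msa = random_msa(rng, 10, 15, gap_p=0.0)
        w0 = compute_weights(msa, delta=0.8)
        k = 4
        dup = MSA(
            ids=msa.ids + tuple(f"d{i}" for i in range(k)),
            rows=msa.rows + (msa.rows[0],) * k,
        )
        w1 = compute_weights(dup, delta=0.8)
        assert w1.m_eff == pytest.approx(w0.m_eff, rel=0.01)

    def test_filtering_is_order_faithful(self):
        rng = np.random.default_rng(8)
        msa = random_msa(rng, 12, 10, gap_p=0.2)
        perm = rng.permutation(12)
        shuffled = msa.subset_sequences(perm)
        out1, removed1 = filter_sequences(msa, seq_gap_cutoff=0.2)
        out2, removed2 = filter_sequences(shuffled, seq_gap_cutoff=0.2)
        assert set(out1.ids) == set(out2.ids)
        w1 = compute_weights(out1, delta=0.5)
        w2 = compute_weights(out2, delta=0.5)
        m1 = dict(zip(out1.ids, w1.w))
        m2 = dict(zip(out2.ids, w2.w))
        assert m1 == pytest.approx(m2)

    def test_resample_full_factor_recovers_alignment(self):
        rows = tuple(["A" * 10] * 6 + ["C" * 10] * 4)
        msa = MSA(ids=tuple(f"s{i}" for i in range(10)), rows=rows)
        w = compute_weights(msa, delta=0.8)
        out, idx = resample_sequences(msa, w, factor=msa.M / w.m_eff, seed=0)
        assert out.M == msa.M
        assert idx == list(range(msa.M))
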