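"""MIF/rMIF estimation: worked values, brute-force oracles, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_iupac_sequence, random_sequence
from seqmif.mif import (
    MIFProfile,
    PairDistribution,
    RMIFProfile,
    ShiftTooLargeError,
    feature_table,
    mif_profile,
    mif_value,
    mutual_information,
    pair_distribution,
    renyi_rmif,
    rmif_profile,
    shannon_rmif,
    tsallis_rmif,
)
from seqmif.sequence_io import ALPHABET, Sequence

PERIODIC = "ACGTACGTACGTACGTA"  # L = 17, every adjacent pair deterministic


def brute_force_pair_distribution(seq: str, tau: int) -> np.ndarray:
    """Independent oracle: dictionary count over all (i, i+tau) pairs."""
    counts = np.zeros((4, 4))
    for i in range(len(seq) - tau):
        counts[ALPHABET.index(seq[i]), ALPHABET.index(seq[i + tau])] += 1
    return counts / (len(seq) - tau)


def independent_pd(marg1, marg2, tau=1) -> PairDistribution:
    joint = np.outer(marg1, marg2)
    return PairDistribution(tau=tau, joint=joint, marginal_first=joint.sum(1),
                            marginal_second=joint.sum(0), n_pairs=100)


class TestPairDistribution:
    def test_homopolymer(self):
        pd_ = pair_distribution("A" * 8, tau=1)
        expected = np.zeros((4, 4))
        expected[0, 0] = 1.0
        np.testing.assert_array_equal(pd_.joint, expected)
        assert pd_.n_pairs == 7

    def test_periodic_adjacent_pairs(self):
        pd_ = pair_distribution(PERIODIC, tau=1)
        # 16 adjacent pairs: A->C, C->G, G->T, T->A each 4 times
        expected = np.zeros((4, 4))
        for a, b in [("A", "C"), ("C", "G"), ("G", "T"), ("T", "A")]:
            expected[ALPHABET.index(a), ALPHABET.index(b)] = 0.25
        np.testing.assert_allclose(pd_.joint, expected, atol=1e-15)
        np.testing.assert_allclose(pd_.marginal_first, 0.25, atol=1e-15)
        np.testing.assert_allclose(pd_.marginal_second, 0.25, atol=1e-15)

    def test_ambiguous_pair_weight_products(self):
        # "AN": the single pair contributes w_A(A) * w_l(N) = 1/4 per column l
        pd_ = pair_distribution("AN", tau=1)
        expected = np.zeros((4, 4))
        expected[0, :] = 0.25
        np.testing.assert_allclose(pd_.joint, expected, atol=1e-15)
        np.testing.assert_allclose(pd_.marginal_first, [1, 0, 0, 0], atol=1e-15)
        np.testing.assert_allclose(pd_.marginal_second, 0.25, atol=1e-15)

    @pytest.mark.parametrize("seq, tau", [("ACG", 3), ("ACG", 5), ("A", 1)])
    def test_shift_too_large(self, seq, tau):
        with pytest.raises(ShiftTooLargeError):
            pair_distribution(seq, tau)

    def test_marginals_are_joint_sums(self, rng):
        for _ in range(20):
            s = random_iupac_sequence(rng, int(rng.integers(10, 60)))
            tau = int(rng.integers(1, 5))
            pd_ = pair_distribution(s, tau)
            np.testing.assert_allclose(pd_.joint.sum(axis=1), pd_.marginal_first,
                                       atol=1e-12)
            np.testing.assert_allclose(pd_.joint.sum(axis=0), pd_.marginal_second,
                                       atol=1e-12)
            assert abs(pd_.joint.sum() - 1.0) < 1e-12

    def test_brute_force_oracle_unambiguous(self, rng):
        for _ in range(50):
            s = random_sequence(rng, int(rng.integers(5, 80)))
            tau = int(rng.integers(1, min(4, len(s))))
            oracle = brute_force_pair_distribution(s, tau)
            np.testing.assert_allclose(pair_distribution(s, tau).joint, oracle,
                                       atol=1e-12)


class TestResolvedFunctions:
    def test_shannon_homopolymer_zero(self):
        assert np.array_equal(shannon_rmif(pair_distribution("A" * 8, 1)),
                              np.zeros(4))

    def test_shannon_periodic_half_bit_each(self):
        vec = shannon_rmif(pair_distribution(PERIODIC, 1))
        np.testing.assert_allclose(vec, 0.5, atol=1e-12)

    def test_shannon_independence_zero(self, rng):
        p = rng.dirichlet(np.ones(4))
        q = rng.dirichlet(np.ones(4))
        np.testing.assert_allclose(shannon_rmif(independent_pd(p, q)), 0.0,
                                   atol=1e-12)

    def test_renyi_periodic_units(self):
        vec = renyi_rmif(pair_distribution(PERIODIC, 1), alpha=2.0)
        np.testing.assert_allclose(vec, 1.0, atol=1e-12)

    def test_renyi_homopolymer(self):
        vec = renyi_rmif(pair_distribution("A" * 8, 1), alpha=2.0)
        np.testing.assert_allclose(vec, [1, 0, 0, 0], atol=1e-15)

    def test_renyi_independent_reduces_to_first_marginal(self, rng):
        # sum_l p(k)^2 q(l)^2 / (p(k) q(l)) = p(k) when the joint factorizes
        p = rng.dirichlet(np.ones(4))
        q = rng.dirichlet(np.ones(4))
        np.testing.assert_allclose(
            renyi_rmif(independent_pd(p, q), alpha=2.0), p, atol=1e-12
        )

    def test_renyi_alpha_one_rejected(self):
        with pytest.raises(ValueError, match="[Ss]hannon"):
            renyi_rmif(pair_distribution(PERIODIC, 1), alpha=1.0)

    def test_tsallis_resolved_is_renyi_resolved(self):
        # the two families share the F-quantity; one code path, bit-identical
        assert tsallis_rmif is renyi_rmif


class TestScalarValues:
    @pytest.mark.parametrize(
        "seq, tau, family, alpha, expected",
        [
            (PERIODIC, 1, "shannon", 2.0, 2.0),  # 4 x 0.5 bits
            ("ACGTACGTACGTACGT", 4, "shannon", 2.0, 2.0),  # 12 pairs (x, x)
            (PERIODIC, 1, "renyi", 2.0, 4.0),
            (PERIODIC, 1, "tsallis", 2.0, 4.0),  # F equal across alpha-families
        ],
    )
    def test_mif_values(self, seq, tau, family, alpha, expected):
        assert mif_value(pair_distribution(seq, tau), family, alpha) == pytest.approx(
            expected, abs=1e-12
        )

    def test_information_transforms(self):
        pd_ = pair_distribution(PERIODIC, 1)
        assert mutual_information(pd_, "renyi", 2.0) == pytest.approx(2.0, abs=1e-12)
        assert mutual_information(pd_, "tsallis", 2.0) == pytest.approx(3.0, abs=1e-12)
        assert mutual_information(pd_, "tsallis", 2.0, convention="printed") == \
            pytest.approx(-3.0, abs=1e-12)

    def test_independent_information_zero_all_families(self, rng):
        p = rng.dirichlet(np.ones(4))
        pd_ = independent_pd(p, p)
        for family in ("shannon", "renyi", "tsallis"):
            assert mutual_information(pd_, family, 2.0) == pytest.approx(0.0, abs=1e-12)

    def test_natural_log_base_rescales_shannon(self):
        pd_ = pair_distribution(PERIODIC, 1)
        bits = mif_value(pd_, "shannon", base=2.0)
        nats = mif_value(pd_, "shannon", base=np.e)
        assert nats == pytest.approx(bits * np.log(2), rel=1e-12)


class TestProfiles:
    def test_feature_counts_tau_max_7(self):
        s = random_sequence(np.random.default_rng(0), 100)
        assert len(rmif_profile(s, 7).flatten()) == 28
        assert len(rmif_profile(s, 7).feature_names()) == 28
        assert len(mif_profile(s, 7).flatten()) == 7

    def test_rmif_flattening_order(self):
        prof = rmif_profile(random_sequence(np.random.default_rng(1), 50), 3)
        assert prof.feature_names()[:4] == [
            "F_shannon_A_1", "F_shannon_A_2", "F_shannon_A_3", "F_shannon_C_1"
        ]
        np.testing.assert_array_equal(prof.flatten()[:3], prof.values[0])

    def test_homopolymer_profile_zero(self):
        np.testing.assert_array_equal(mif_profile("A" * 10, 3).values, np.zeros(3))

    def test_profile_shift_too_large(self):
        with pytest.raises(ShiftTooLargeError):
            mif_profile("ACGTA", 5)

    @given(st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_resolution_consistency(self, seed):
        """Sum over the alphabet of the resolved values reproduces the MIF."""
        rng = np.random.default_rng(seed)
        s = random_iupac_sequence(rng, int(rng.integers(12, 120)))
        tau_max = min(8, len(s) - 1)
        for family, alpha in (("shannon", 2.0), ("renyi", 2.0), ("tsallis", 1.7)):
            r = rmif_profile(s, tau_max, family, alpha)
            m = mif_profile(s, tau_max, family, alpha)
            np.testing.assert_array_equal(r.values.sum(axis=0), m.values)

    def test_shannon_limit_of_renyi(self, rng):
        eps = 1e-3
        for _ in range(20):
            s = random_iupac_sequence(rng, int(rng.integers(20, 100)))
            pd_ = pair_distribution(s, 1)
            i_shannon = mutual_information(pd_, "shannon")
            i_renyi = mutual_information(pd_, "renyi", alpha=1.0 + eps)
            assert abs(i_renyi - i_shannon) < 1e-2

    def test_nonnegativity(self, rng):
        for _ in range(30):
            s = random_iupac_sequence(rng, int(rng.integers(10, 80)))
            pd_ = pair_distribution(s, int(rng.integers(1, 4)))
            assert mutual_information(pd_, "shannon") >= -1e-12
            assert mutual_information(pd_, "renyi", 2.0) >= -1e-12
            assert mutual_information(pd_, "tsallis", 2.0) >= -1e-12

    def test_iid_mif_decays_with_length(self):
        """Plug-in MIF of i.i.d. sequences shrinks toward 0 as L grows."""
        medians = []
        for L in (50, 500, 5000):
            vals = [
                mif_value(pair_distribution(
                    random_sequence(np.random.default_rng(1000 + r), L), 1))
                for r in range(7)
            ]
            medians.append(np.median(vals))
        assert medians[0] > medians[1] > medians[2]
        assert medians[2] < 0.01


class TestFeatureTable:
    def test_columns_and_order(self, rng):
        seqs = [Sequence(f"s{i}", random_sequence(rng, 40), label="x")
                for i in range(3)]
        df = feature_table(seqs, method="rmif", tau_max=4, family="renyi")
        assert list(df.columns[:2]) == ["id", "label"]
        assert df.shape == (3, 2 + 16)
        assert df.columns[2] == "F_renyi_A_1"

    def test_on_short_modes(self, rng):
        seqs = [Sequence("long", random_sequence(rng, 50)), Sequence("short", "ACG")]
        with pytest.raises(ShiftTooLargeError, match="short"):
            feature_table(seqs, method="mif", tau_max=5)
        df = feature_table(seqs, method="mif", tau_max=5, on_short="nan")
        assert df.loc[1, df.columns[2:]].isna().all()
        assert not df.loc[0, df.columns[2:]].isna().any()
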