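"""Mutative factor and the two correlation flavours."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import cmca
from cmca.errors import DomainError, ValidationError


def freq_from_columns(*columns: str) -> cmca.FrequencyMatrix:
    n = len(columns[0])
    rows = tuple("".join(col[i] for col in columns) for i in range(n))
    alignment = cmca.Alignment(tuple(f"s{i}" for i in range(n)), rows)
    return cmca.position_frequencies(cmca.encode(alignment))


class TestAminoAcidTypes:
    def test_counts_distinct_symbols_including_gap(self):
        freq = freq_from_columns("A" * 10, "AAAAACCCC-")
        n = cmca.amino_acid_types(freq)
        assert n.tolist() == [1, 3]


class TestMutativeFactor:
    def test_maximum_at_average_frequency(self):
        # N=100, n=20: average frequency is 5, maximum value n-1 = 19
        assert cmca.mutative_factor(5, 100, 20) == pytest.approx(19.0)
        values = cmca.mutative_factor(np.arange(101), 100, 20)
        assert values.max() == pytest.approx(19.0)
        assert int(values.argmax()) == 5

    @pytest.mark.parametrize("n_sequences", [10, 100, 240])
    def test_invariant_column_scores_zero(self, n_sequences):
        f = np.arange(n_sequences + 1)
        assert (cmca.mutative_factor(f, n_sequences, 1) == 0).all()

    def test_direct_evaluation(self):
        # n=2 at N=100: average is 50, so t(60) = 1 / 11
        assert cmca.mutative_factor(60, 100, 2) == pytest.approx(1 / 11)

    @pytest.mark.parametrize("n_sequences", [10, 100, 240])
    @pytest.mark.parametrize("n_types", range(1, 22))
    def test_constraint_suite(self, n_sequences, n_types):
        """Finite everywhere, peak of height n-1 at the average frequency,
        strict decay away from it."""
        f = np.arange(n_sequences + 1)
        values = cmca.mutative_factor(f, n_sequences, n_types)
        assert np.isfinite(values).all()
        # at the (real-valued) average frequency the factor is exactly n - 1
        mean = n_sequences / n_types
        assert cmca.mutative_factor(mean, n_sequences, n_types) == pytest.approx(
            n_types - 1
        )
        assert values.max() <= n_types - 1 + 1e-12
        # strict monotone decay with |f - N/n| over the integers
        distance = np.abs(f - mean)
        order = np.argsort(distance)
        sorted_values = values[order]
        if n_types > 1:
            assert (np.diff(sorted_values) < 1e-15).all()

    def test_bounded_by_twenty(self):
        f = np.arange(241)
        for n_types in range(1, 22):
            assert cmca.mutative_factor(f, 240, n_types).max() <= 20.0

    @pytest.mark.parametrize(
        "f, n_sequences, n_types",
        [(-1, 100, 5), (101, 100, 5), (5, 100, 0), (5, 100, 22), (5, 0, 5)],
    )
    def test_domain_errors(self, f, n_sequences, n_types):
        with pytest.raises(DomainError):
            cmca.mutative_factor(f, n_sequences, n_types)


class TestMutationMatrix:
    def test_conserved_column_all_zero(self):
        freq = freq_from_columns("A" * 10, "AAAAACCCC-")
        t = cmca.mutation_matrix(freq)
        assert (t.values[:, 0] == 0).all()
        assert t.n_types.tolist() == [1, 3]

    def test_balanced_two_state_column(self):
        # 50/50 split at N=100: both present symbols sit at the average
        freq = freq_from_columns("A" * 50 + "C" * 50, "ACDEF" * 20)
        t = cmca.mutation_matrix(freq)
        idx = cmca.PROTEIN.index
        assert t.values[idx["A"], 0] == pytest.approx(1.0)
        assert t.values[idx["C"], 0] == pytest.approx(1.0)
        assert t.values[idx["D"], 0] == pytest.approx(1 / 51)

    def test_column_maximum_bounded_by_types(self, pdz_analysis):
        t = cmca.mutation_matrix(pdz_analysis["freq"])
        col_max = t.values.max(axis=0)
        assert (col_max <= t.n_types - 1 + 1e-12).all()


class TestProfileCorrelation:
    def test_identical_columns_correlate_perfectly(self):
        rng = np.random.default_rng(3)
        column = rng.random(21)
        profile = np.column_stack([column, column, rng.random(21)])
        r = cmca.profile_correlation(profile)
        assert r.values[0, 1] == pytest.approx(1.0)

    def test_brute_force_oracle(self):
        """Matrix result equals per-pair Pearson on random 21 x 6 profiles."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            profile = rng.random((21, 6))
            r = cmca.profile_correlation(profile)
            for i in range(6):
                for j in range(6):
                    expected = stats.pearsonr(profile[:, i], profile[:, j])[0]
                    assert r.values[i, j] == pytest.approx(
                        expected, abs=1e-10
                    )

    def test_zero_variance_column_flagged(self):
        profile = np.column_stack([np.full(21, 2.0), np.arange(21.0)])
        r = cmca.profile_correlation(profile)
        assert r.undefined_positions == (0,)
        assert r.values[0, 1] == 0.0
        assert r.values[0, 0] == 1.0

    def test_single_position_rejected(self):
        with pytest.raises(ValidationError):
            cmca.profile_correlation(np.ones((21, 1)))

    @given(seed=st.integers(0, 1000))
    def test_symmetry_unit_diagonal_and_range(self, seed):
        rng = np.random.default_rng(seed)
        profile = rng.random((21, 8))
        r = cmca.profile_correlation(profile)
        np.testing.assert_allclose(r.values, r.values.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(r.values), 1.0, atol=1e-12)
        assert (np.abs(r.values) <= 1 + 1e-9).all()

    @given(seed=st.integers(0, 1000), scale=st.floats(0.01, 100.0))
    def test_normalisation_invariance(self, seed, scale):
        """Positive scaling and the covariance divisor leave r unchanged."""
        rng = np.random.default_rng(seed)
        profile = rng.random((21, 5))
        base = cmca.profile_correlation(profile).values
        scaled = cmca.profile_correlation(profile * scale).values
        sample = cmca.profile_correlation(profile, ddof=1).values
        np.testing.assert_allclose(scaled, base, atol=1e-12)
        np.testing.assert_allclose(sample, base, atol=1e-12)


class TestConservationCorrelation:
    def test_identical_count_profiles(self):
        # two columns with counts {A:9, C:1} in the same rows
        freq = freq_from_columns("A" * 9 + "C", "A" * 9 + "C")
        r = cmca.conservation_correlation(freq)
        assert r.values[0, 1] == pytest.approx(1.0)

    def test_random_columns_weakly_correlated(self):
        # i.i.d. uniform columns carry no coupling signal; over the 20
        # amino-acid profile entries their correlations centre on 0
        # (the all-zero gap row of a gapless family is excluded — it is
        # shared structure, not signal)
        rng = np.random.default_rng(5)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        rows = tuple(
            "".join(rng.choice(aa) for _ in range(12)) for _ in range(400)
        )
        alignment = cmca.Alignment(
            tuple(f"s{i}" for i in range(400)), rows
        )
        freq = cmca.position_frequencies(cmca.encode(alignment))
        r = cmca.conservation_correlation(freq, include_gap_row=False)
        off = r.values[~np.eye(12, dtype=bool)]
        assert abs(np.mean(off)) < 0.1
        assert np.abs(off).mean() < 0.3

    def test_conserved_family_more_correlated_than_random(self):
        """A conserved family with shared indel content shows broadly high
        conservation correlations; an i.i.d. uniform family does not."""
        spec = cmca.FamilySpec(
            n_sequences=200,
            n_columns=15,
            background=0.97,
            gap_columns=tuple((c, 0.5) for c in range(1, 16)),
            seed=7,
        )
        alignment, _ = cmca.generate_family(spec)
        freq, _ = cmca.reduce_gaps(
            cmca.position_frequencies(cmca.encode(alignment))
        )
        conserved = cmca.conservation_correlation(freq)
        rng = np.random.default_rng(8)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        rows = tuple(
            "".join(rng.choice(aa) for _ in range(15)) for _ in range(200)
        )
        uniform_freq = cmca.position_frequencies(
            cmca.encode(cmca.Alignment(tuple(f"s{i}" for i in range(200)), rows))
        )
        uniform = cmca.conservation_correlation(uniform_freq)
        off = ~np.eye(15, dtype=bool)
        assert np.median(conserved.values[off]) > np.median(uniform.values[off])


class TestMutationCorrelation:
    def test_perfectly_covarying_pair(self):
        spec = cmca.FamilySpec(
            n_sequences=200,
            n_columns=6,
            background=1.0,
            coupled_sets=((2, 5),),
            states_per_set=3,
            seed=42,
        )
        alignment, _ = cmca.generate_family(spec)
        freq, _ = cmca.reduce_gaps(
            cmca.position_frequencies(cmca.encode(alignment))
        )
        r = cmca.mutation_correlation(freq)
        assert r.values[1, 4] == pytest.approx(1.0, abs=1e-9)

    def test_conserved_positions_are_undefined(self):
        freq = freq_from_columns("A" * 10, "AAAAACCCC-")
        r = cmca.mutation_correlation(freq)
        assert 0 in r.undefined_positions
        assert r.values[0, 1] == 0.0

    def test_planted_pair_ranks_top_percentile(self):
        spec = cmca.FamilySpec(
            n_sequences=150,
            n_columns=40,
            background=0.9,
            coupled_sets=((10, 30),),
            states_per_set=4,
            seed=21,
        )
        alignment, _ = cmca.generate_family(spec)
        freq, _ = cmca.reduce_gaps(
            cmca.position_frequencies(cmca.encode(alignment))
        )
        r = cmca.mutation_correlation(freq)
        tri = r.values[np.tril_indices(40, k=-1)]
        planted = r.values[29, 9]
        assert planted >= np.quantile(tri, 0.99)

    def test_gap_row_switch_changes_profile_scope(self, pdz_analysis):
        with_gap = cmca.mutation_correlation(
            pdz_analysis["freq"], include_gap_row=True
        )
        without_gap = cmca.mutation_correlation(
            pdz_analysis["freq"], include_gap_row=False
        )
        assert with_gap.values.shape == without_gap.values.shape
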