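"""Synthetic fragment generator: degradation model, sampling, proteomes."""

import numpy as np
import pytest

from fragid import fragsim
from fragid.errors import EmptyInputError, InvalidInputError, InvalidParameterError
from fragid.fragsim import (
    DegradationParams,
    chain_length_profile,
    degradation_from_resolution,
    simulate_fragments,
    simulate_proteome,
)


class TestDegradationModel:
    @pytest.mark.parametrize(
        "resolution,scale_k,expected_len",
        [(2.5, 150, 60), (9.0, 150, 17), (5.0, 150, 30)],
    )
    def test_mean_length_inverse_in_resolution(self, resolution, scale_k, expected_len):
        p = degradation_from_resolution(resolution, scale_k=scale_k)
        assert p.mean_fragment_length == expected_len

    def test_error_rate_linear_and_clamped(self):
        p = degradation_from_resolution(2.5, error_base=0.10, error_slope=0.08)
        assert p.substitution_error_rate == pytest.approx(0.10)
        worse = degradation_from_resolution(9.0, error_base=0.10, error_slope=0.08)
        assert worse.substitution_error_rate == pytest.approx(0.10 + 0.08 * 6.5)
        extreme = degradation_from_resolution(100.0)
        assert extreme.substitution_error_rate == 0.95

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_invalid_resolution_rejected(self, bad):
        with pytest.raises(InvalidParameterError):
            degradation_from_resolution(bad)
        with pytest.raises(InvalidParameterError):
            degradation_from_resolution(2.5, scale_k=bad)

    def test_param_validation(self):
        with pytest.raises(InvalidParameterError):
            DegradationParams(resolution=2.5, mean_fragment_length=60,
                              substitution_error_rate=1.0)
        with pytest.raises(InvalidParameterError):
            DegradationParams(resolution=2.5, mean_fragment_length=60,
                              coverage_fraction=0.0)


class TestSimulateFragments:
    def test_zero_noise_fragments_are_exact_substrings(self, reference):
        params = DegradationParams(resolution=2.5, mean_fragment_length=40)
        fs = simulate_fragments(reference, params, n_fragments=30, seed=1)
        for f in fs:
            s, e = f.source_span
            assert f.sequence == reference[s:e]

    def test_seed_reproducibility_and_prefix_stability(self, reference):
        params = degradation_from_resolution(4.0)
        a = simulate_fragments(reference, params, n_fragments=12, seed=9)
        b = simulate_fragments(reference, params, n_fragments=12, seed=9)
        assert [(f.id, f.sequence, f.source_span) for f in a] == [
            (f.id, f.sequence, f.source_span) for f in b
        ]
        # growing n_fragments never reshuffles earlier fragments
        c = simulate_fragments(reference, params, n_fragments=20, seed=9)
        assert [f.sequence for f in c][:12] == [f.sequence for f in a]

    def test_empirical_mean_length_matches_target(self):
        long_ref = fragsim.synthetic_reference(10_000, seed=3)
        params = DegradationParams(resolution=2.5, mean_fragment_length=60)
        fs = simulate_fragments(long_ref, params, n_fragments=4000, seed=4)
        mean_len = np.mean([len(f) for f in fs])
        assert abs(mean_len - 60) < 3  # SE ≈ 0.85 at this sample size

    def test_profile_columns_sum_to_one_and_argmax_is_emitted(self, reference):
        params = DegradationParams(
            resolution=5.0, mean_fragment_length=30, substitution_error_rate=0.3
        )
        fs = simulate_fragments(reference, params, n_fragments=10, seed=2)
        for f in fs:
            assert np.allclose(f.profile.sum(axis=1), 1.0)
            from fragid.alphabet import AA

            called = [AA[i] for i in f.profile.argmax(axis=1)]
            assert "".join(called) == f.sequence

    def test_degradation_monotonicity_over_seeds(self, reference):
        """Mean fragment length strictly falls from 3 Å to 6 Å, paired by seed."""
        p3 = degradation_from_resolution(3.0)
        p6 = degradation_from_resolution(6.0)
        wins = 0
        for seed in range(50):
            f3 = simulate_fragments(reference, p3, n_fragments=15, seed=seed)
            f6 = simulate_fragments(reference, p6, n_fragments=15, seed=seed)
            m3 = np.mean([len(f) for f in f3])
            m6 = np.mean([len(f) for f in f6])
            wins += m3 > m6
        assert wins >= 48  # strict dominance up to rare sampling ties

    def test_error_contracts(self, reference):
        with pytest.raises(InvalidInputError):
            simulate_fragments("A", DegradationParams(2.5, 10), n_fragments=1)
        with pytest.raises(InvalidParameterError):
            simulate_fragments(reference, DegradationParams(2.5, 10), n_fragments=0)


class TestSimulateProteome:
    def test_zero_divergence_paralog_identical_but_relabelled(self, reference):
        db = simulate_proteome(0, (50, 60), target={"sequence": reference},
                               paralog_divergence=0.0, seed=1)
        assert len(db) == 2
        target, paralog = db.records
        assert paralog.sequence == target.sequence
        assert paralog.description != target.description
        from fragid.identify import is_dlst_match

        assert is_dlst_match(target.description)
        assert not is_dlst_match(paralog.description)

    def test_decoy_composition_near_uniform(self, reference):
        db = simulate_proteome(500, (100, 200), target={"sequence": reference}, seed=7)
        from collections import Counter

        pooled = Counter("".join(r.sequence for r in db.records if r.id.startswith("DECOY")))
        total = sum(pooled.values())
        for aa in fragsim.AA:
            assert abs(pooled[aa] / total - 0.05) < 0.01

    def test_size_residues_and_determinism(self, reference):
        db1 = simulate_proteome(20, (50, 80), target={"sequence": reference}, seed=3)
        db2 = simulate_proteome(20, (50, 80), target={"sequence": reference}, seed=3)
        assert [r.sequence for r in db1] == [r.sequence for r in db2]
        assert db1.size_residues == sum(len(r.sequence) for r in db1.records)

    def test_homologs_carry_matching_labels(self, standard_db):
        from fragid.identify import is_dlst_match

        homs = [r for r in standard_db if r.id.startswith("HOMOLOG")]
        assert len(homs) == 10
        assert all(is_dlst_match(r.description) for r in homs)

    def test_bad_length_range_rejected(self, reference):
        with pytest.raises(InvalidParameterError):
            simulate_proteome(5, (0, 10), target={"sequence": reference})
        with pytest.raises(InvalidParameterError):
            simulate_proteome(5, (20, 10), target={"sequence": reference})


class TestChainLengthProfile:
    def _set(self, lengths):
        frags = [
            fragsim.Fragment(f"f{i}", "A" * n) for i, n in enumerate(lengths)
        ]
        return fragsim.FragmentSet(frags)

    def test_single_bin(self):
        assert chain_length_profile(self._set([5, 5, 5])) == [1.0, 0.0, 0.0]

    def test_residue_weighting(self):
        fractions = chain_length_profile(self._set([5, 195]))
        assert fractions == pytest.approx([0.025, 0.0, 0.975])

    def test_fractions_sum_to_one(self):
        fractions = chain_length_profile(self._set([3, 17, 42, 120, 7]))
        assert sum(fractions) == pytest.approx(1.0)

    def test_long_chain_fraction_falls_with_degradation(self):
        """Residue share of >100-residue chains shrinks as fragments shorten."""
        long_ref = fragsim.synthetic_reference(2000, seed=8)
        means = []
        for mean_len in (120, 60, 30, 8):
            vals = []
            for seed in range(25):
                fs = simulate_fragments(
                    long_ref,
                    DegradationParams(resolution=2.5, mean_fragment_length=mean_len),
                    n_fragments=40,
                    seed=seed,
                )
                vals.append(chain_length_profile(fs)[2])
            means.append(np.mean(vals))
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_bin_validation_and_empty_set(self):
        with pytest.raises(EmptyInputError):
            chain_length_profile(fragsim.FragmentSet([]))
        with pytest.raises(InvalidParameterError):
            chain_length_profile(self._set([5]), bins=[(1, 10), (12, float("inf"))])
        with pytest.raises(InvalidParameterError):
            chain_length_profile(self._set([5]), bins=[(1, 10), (11, 100)])
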