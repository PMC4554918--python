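"""Donor-window extraction, PWM/maxent training, scoring and serialization."""

import itertools
import math

import numpy as np
import pytest

import slimsplice as ss
from slimsplice.donors import (
    DonorWindow,
    SpliceScoreModel,
    default_maxent_constraints,
    load_model,
    save_model,
)


def W(seq):
    return DonorWindow(seq)


class TestExtractWindow:
    def test_terminal_donor_uses_flank(self):
        w = ss.extract_donor_window("TTTACG", "GTAAGTCC", cut=6)
        assert w.seq == "ACGGTAAGT"

    def test_internal_donor_uses_exon_remainder(self):
        w = ss.extract_donor_window("TTTACGGTAAGTCC", "", cut=6)
        assert w.seq == "ACGGTAAGT"

    def test_insufficient_exonic_context(self):
        with pytest.raises(ValueError, match="exonic"):
            ss.extract_donor_window("TTTACG", "GTAAGTCC", cut=2)

    def test_insufficient_downstream_context(self):
        with pytest.raises(ValueError, match="downstream"):
            ss.extract_donor_window("TTTACG", "GTA", cut=6)

    def test_n_flags_window_invalid(self):
        w = ss.extract_donor_window("TTTACG", "GTANGT", cut=6)
        assert not w.valid


class TestTrainPwm:
    def test_identical_windows_no_pseudocount_give_indicators(self):
        model = ss.train_pwm([W("ACGGTAAGT")] * 4, pseudocount=0.0)
        for pos, base in enumerate("ACGGTAAGT"):
            col = model.freqs[pos]
            assert col["ACGT".index(base)] == 1.0
            assert col.sum() == pytest.approx(1.0)

    def test_pseudocount_hand_calculation(self):
        # counts A:3, C:1 at the single position, alpha = 0.5
        model = ss.train_pwm([W("A"), W("A"), W("A"), W("C")],
                             pseudocount=0.5, n_positions=1)
        assert model.freqs[0] == pytest.approx([3.5 / 6, 1.5 / 6, 0.5 / 6, 0.5 / 6])

    def test_columns_sum_to_one(self, pwm_model):
        assert np.allclose(pwm_model.freqs.sum(axis=1), 1.0, atol=1e-9)

    def test_no_valid_windows_is_an_error(self):
        with pytest.raises(ValueError):
            ss.train_pwm([W("NNNNNNNNN")])

    def test_recovers_generating_frequencies(self):
        cfg = ss.default_config()
        positives, _ = ss.simulate_donor_training_set(cfg["donor_model"], 2000, seed=2)
        model = ss.train_pwm(positives)
        freq = np.asarray(cfg["donor_model"], dtype=float)
        forced = freq.copy()
        forced[3] = [0, 0, 1, 0]  # sampling forces G
        forced[4] = [0, 0, 0, 1]  # and T at the donor dinucleotide
        tv = 0.5 * np.abs(model.freqs - forced).sum(axis=1)
        assert tv.max() < 0.05


class TestScoring:
    def test_uniform_model_scores_zero(self):
        model = SpliceScoreModel(kind="pwm", freqs=np.full((9, 4), 0.25))
        assert ss.score_window(model, W("ACGGTAAGT")) == pytest.approx(0.0)

    def test_own_sequence_under_indicator_pwm_scores_18_bits(self):
        model = ss.train_pwm([W("ACGGTAAGT")], pseudocount=0.0)
        assert ss.score_window(model, W("ACGGTAAGT")) == pytest.approx(18.0)

    def test_consensus_maximizes_score(self, pwm_model):
        consensus = "".join("ACGT"[i] for i in pwm_model.freqs.argmax(axis=1))
        best = ss.score_window(pwm_model, W(consensus))
        rng = np.random.default_rng(0)
        for _ in range(50):
            other = "".join(rng.choice(list("ACGT"), size=9))
            assert ss.score_window(pwm_model, W(other)) <= best + 1e-12

    def test_invalid_window_returns_none(self, pwm_model):
        assert ss.score_window(pwm_model, W("ACGGTANGT")) is None

    def test_decoy_background_model(self, pwm_model):
        decoy = SpliceScoreModel(kind="pwm", freqs=np.full((9, 4), 0.25))
        w = W("ACGGTAAGT")
        assert ss.score_window(pwm_model, w, background=decoy) == pytest.approx(
            ss.score_window(pwm_model, w)
        )

    def test_scores_invariant_under_training_set_duplication(self, locus):
        # exact for the maximum-likelihood frequencies (pseudocount 0)
        once = ss.train_pwm(locus.donors, pseudocount=0.0)
        twice = ss.train_pwm(list(locus.donors) * 2, pseudocount=0.0)
        for w in locus.donors:
            assert ss.score_window(once, w) == pytest.approx(
                ss.score_window(twice, w), abs=1e-12
            )


class TestMaxent:
    def test_singleton_constraints_reduce_to_pwm(self):
        cfg = ss.default_config()
        positives, _ = ss.simulate_donor_training_set(cfg["donor_model"], 60, seed=3)
        pwm = ss.train_pwm(positives)
        maxent = ss.train_maxent(positives, constraints=[(i,) for i in range(9)])
        rng = np.random.default_rng(1)
        for _ in range(100):
            w = W("".join(rng.choice(list("ACGT"), size=9)))
            assert ss.score_window(maxent, w) == pytest.approx(
                ss.score_window(pwm, w), abs=1e-6
            )

    def test_pair_constraint_matches_enumeration_ipf_oracle(self):
        rng = np.random.default_rng(9)
        windows = [W("".join(rng.choice(list("ACG"), size=3))) for _ in range(40)]
        alpha = 0.5
        constraints = [(0,), (1,), (2,), (0, 1)]
        model = ss.train_maxent(windows, constraints=constraints,
                                pseudocount=alpha, n_positions=3, tol=1e-12)

        # oracle: IPF over the explicitly enumerated 64 three-mers
        seqs = ["".join(t) for t in itertools.product("ACGT", repeat=3)]
        m = 4 * alpha
        n = len(windows)

        def emp_marginal(cons):
            shape = (4,) * len(cons)
            counts = np.zeros(shape)
            for w in windows:
                counts[tuple("ACGT".index(w.seq[p]) for p in cons)] += 1
            return (counts + m / 4 ** len(cons)) / (n + m)

        p = np.full(64, 1 / 64)
        for _ in range(2000):
            for cons in constraints:
                target = emp_marginal(cons)
                marg = np.zeros_like(target)
                for k, s in enumerate(seqs):
                    marg[tuple("ACGT".index(s[q]) for q in cons)] += p[k]
                for k, s in enumerate(seqs):
                    idx = tuple("ACGT".index(s[q]) for q in cons)
                    p[k] *= target[idx] / marg[idx]
        p /= p.sum()

        from slimsplice.donors import log2_probability

        for k, s in enumerate(seqs):
            assert 2 ** log2_probability(model, s) == pytest.approx(p[k], abs=1e-6)

    def test_fitted_pair_marginal_satisfies_constraint(self):
        cfg = ss.default_config()
        positives, _ = ss.simulate_donor_training_set(cfg["donor_model"], 80, seed=5)
        model = ss.train_maxent(positives, tol=1e-10)
        from slimsplice.donors import _empirical_marginals, _joint_from_factors

        target = _empirical_marginals(positives, model.constraints, model.pseudocount)
        joint = _joint_from_factors(model.factors, 9)
        joint /= joint.sum()
        for cons in model.constraints:
            axes = tuple(i for i in range(9) if i not in cons)
            assert np.abs(joint.sum(axis=axes) - target[cons]).max() < 1e-8

    def test_missing_singleton_constraint_rejected(self):
        with pytest.raises(ValueError, match="singleton"):
            ss.train_maxent([W("ACGGTAAGT")], constraints=[(0,), (1,)])

    def test_default_constraints_are_singletons_plus_adjacent_pairs(self):
        cons = default_maxent_constraints(9)
        assert [(i,) for i in range(9)] == cons[:9]
        assert [(i, i + 1) for i in range(8)] == cons[9:]


class TestStats:
    def test_known_scores_via_table_model(self):
        model = SpliceScoreModel(
            kind="table", table={"AAAAAAAAA": 7.0, "CCCCCCCCC": 8.0, "GGGGGGGGG": 9.0}
        )
        stats = ss.donor_score_stats(
            [W("AAAAAAAAA"), W("CCCCCCCCC"), W("GGGGGGGGG")], model
        )
        assert (stats.mean, stats.sd, stats.n) == (8.0, 1.0, 3)

    def test_identical_scores_have_zero_sd(self):
        model = SpliceScoreModel(kind="table", table={"AAAAAAAAA": 5.5})
        stats = ss.donor_score_stats([W("AAAAAAAAA")] * 4, model)
        assert stats.sd == 0.0

    def test_matches_two_pass_oracle_on_random_windows(self, pwm_model):
        rng = np.random.default_rng(12)
        windows = [W("".join(rng.choice(list("ACGT"), size=9))) for _ in range(100)]
        stats = ss.donor_score_stats(windows, pwm_model)
        scores = [ss.score_window(pwm_model, w) for w in windows]
        mean = sum(scores) / len(scores)
        sd = math.sqrt(sum((s - mean) ** 2 for s in scores) / (len(scores) - 1))
        assert stats.mean == pytest.approx(mean)
        assert stats.sd == pytest.approx(sd)

    def test_fewer_than_two_windows_is_an_error(self, pwm_model):
        with pytest.raises(ValueError):
            ss.donor_score_stats([W("ACGGTAAGT")], pwm_model)


class TestSerialization:
    def test_pwm_round_trips_bit_exactly(self, tmp_path, pwm_model, locus):
        path = tmp_path / "pwm.tsv"
        save_model(pwm_model, path)
        back = load_model(path)
        assert np.array_equal(back.freqs, pwm_model.freqs)
        for w in locus.donors:
            assert ss.score_window(back, w) == ss.score_window(pwm_model, w)

    def test_maxent_round_trips_bit_exactly(self, tmp_path, locus):
        model = ss.train_maxent(locus.donors, tol=1e-8)
        path = tmp_path / "maxent.tsv"
        save_model(model, path)
        back = load_model(path)
        for w in locus.donors:
            assert ss.score_window(back, w) == ss.score_window(model, w)

    def test_table_round_trip(self, tmp_path):
        model = SpliceScoreModel(kind="table", table={"ACGGTAAGT": 8.25})
        path = tmp_path / "table.tsv"
        save_model(model, path)
        assert ss.score_window(load_model(path), W("ACGGTAAGT")) == 8.25
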