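"""Soft-sequence representation, losses, gradients, and the design loop."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from solbinder import seqdesign
from solbinder.aaindex import ALPHABET, oriented_index
from solbinder.seqdesign import (
    LossWeights,
    NonFiniteLossError,
    SoftSequence,
    StageSchedule,
    TrajectoryRecord,
    combined_loss,
    design_3stage,
    init_logits,
    one_hot,
    probs_grad_to_logits,
    select_best,
    solubility_loss,
    solubility_loss_grad,
)
from solbinder.surrogate import OracleOutput, SurrogateOracle

P53 = "ETFSDLWKLLPEN"


def lookup_mean(sequence, table):
    """Independent oracle: plain per-residue lookup-and-average."""
    return sum(table.normalized[aa] for aa in sequence) / len(sequence)


# ---------------------------------------------------------------------------
# initialization and probabilities
# ---------------------------------------------------------------------------

class TestInitLogits:
    def test_deterministic_per_seed(self):
        a = init_logits(13, seed=1)
        b = init_logits(13, seed=1)
        np.testing.assert_array_equal(a.logits, b.logits)

    def test_seed_sensitivity(self):
        assert not np.array_equal(init_logits(13, 1).logits, init_logits(13, 2).logits)

    def test_pd1_length_17(self):
        assert init_logits(17, seed=5).logits.shape == (17, 20)

    def test_invalid_length_rejected(self):
        with pytest.raises(ValueError):
            init_logits(0, seed=1)


class TestToProbs:
    def test_zero_logits_give_uniform_rows(self):
        s = SoftSequence(np.zeros((4, 20)))
        np.testing.assert_allclose(s.probs, np.full((4, 20), 1 / 20), atol=1e-15)

    def test_hard_mode_is_one_hot_at_argmax(self):
        s = init_logits(13, seed=3)
        hard = SoftSequence(s.logits, temperature=0.01, mode="hard")
        probs = hard.probs
        assert np.all(np.sum(probs == 1.0, axis=1) == 1)
        np.testing.assert_array_equal(
            np.argmax(probs, axis=1), np.argmax(s.logits, axis=1)
        )

    def test_temperature_softmax_matches_hand_computation(self):
        logits = np.zeros((2, 20))
        logits[0, :3] = [1.0, 2.0, 0.5]
        logits[1, 5] = -1.0
        T = 0.5
        s = SoftSequence(logits, temperature=T, mode="temp")
        # independent hand computation with math.exp
        for i in range(2):
            exps = [math.exp(z / T) for z in logits[i]]
            total = sum(exps)
            np.testing.assert_allclose(s.probs[i], [e / total for e in exps],
                                       rtol=1e-12)

    def test_rows_are_distributions(self):
        s = init_logits(8, seed=11)
        np.testing.assert_allclose(s.probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(s.probs >= 0)

    def test_non_finite_logits_rejected(self):
        logits = np.zeros((2, 20))
        logits[1, 4] = np.nan
        with pytest.raises(NonFiniteLossError):
            SoftSequence(logits).probs


# ---------------------------------------------------------------------------
# solubility loss
# ---------------------------------------------------------------------------

class TestSolubilityLoss:
    @pytest.mark.parametrize("name", ["hydrophobicity", "hydropathy", "swi"])
    def test_one_hot_equals_lookup_mean(self, oriented_tables, name):
        table = oriented_tables[name]
        s = SoftSequence(one_hot(P53) * 10.0, mode="hard")
        assert solubility_loss(s, table) == pytest.approx(
            lookup_mean(P53, table), abs=1e-12
        )

    def test_zero_residue_homopolymer_has_zero_loss(self, hydropathy):
        s = SoftSequence(one_hot("R" * 13) * 10.0, mode="hard")
        assert solubility_loss(s, hydropathy) == 0.0

    def test_uniform_probs_give_mean_of_table(self, hydropathy):
        s = SoftSequence(np.zeros((7, 20)))
        expected = np.mean([hydropathy.normalized[aa] for aa in ALPHABET])
        assert solubility_loss(s, hydropathy) == pytest.approx(expected, abs=1e-12)

    def test_unnormalized_table_rejected(self):
        from solbinder.aaindex import TableStateError, load_index

        with pytest.raises(TableStateError):
            solubility_loss(init_logits(5, 1), load_index("hydropathy"))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000), alpha=st.floats(0, 1))
    def test_bounded_and_linear_in_probs(self, hydropathy, seed, alpha):
        """Loss lies in [0,1]; mixtures of distributions mix losses linearly."""
        rng = np.random.default_rng(seed)
        f = hydropathy.as_array()
        P = rng.dirichlet(np.ones(20), size=6)
        Q = rng.dirichlet(np.ones(20), size=6)
        loss = lambda probs: float(np.mean(probs @ f))
        mix = alpha * P + (1 - alpha) * Q
        assert 0.0 <= loss(mix) <= 1.0
        assert loss(mix) == pytest.approx(
            alpha * loss(P) + (1 - alpha) * loss(Q), abs=1e-12
        )

    def test_geometric_variant_at_one_hot(self, hydropathy):
        seq = "AWFC"  # all non-zero table values
        s = SoftSequence(one_hot(seq) * 10.0, mode="hard")
        expected = math.exp(
            sum(math.log(hydropathy.normalized[aa]) for aa in seq) / len(seq)
        )
        assert solubility_loss(s, hydropathy, mean="geometric") == pytest.approx(
            expected, rel=1e-9
        )


# ---------------------------------------------------------------------------
# combined loss and best-sequence selection
# ---------------------------------------------------------------------------

class TestCombinedLoss:
    def out(self, interface=0.4, confidence=1.0):
        return OracleOutput(losses={"interface": interface, "confidence": confidence})

    def test_zero_solubility_weight_gives_pure_oracle_loss(self):
        w = LossWeights(solubility_weight=0.0,
                        oracle_weights={"interface": 1.0, "confidence": 1.0})
        total, comps = combined_loss(self.out(), sol=0.9, w=w)
        assert total == pytest.approx(1.4)
        assert comps["solubility"] == 0.9

    def test_solubility_only(self):
        w = LossWeights(solubility_weight=1.0, oracle_weights={})
        total, _ = combined_loss(self.out(), sol=0.37, w=w)
        assert total == pytest.approx(0.37)

    def test_hand_computed_weighted_sum(self):
        w = LossWeights(solubility_weight=0.0,
                        oracle_weights={"interface": 0.5, "confidence": 0.3})
        total, _ = combined_loss(self.out(interface=0.4, confidence=1.0), 0.0, w)
        assert total == pytest.approx(0.5)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(solubility_weight=-0.1)


class TestSelectBest:
    @staticmethod
    def rec(i, stage, loss, seq="A"):
        return TrajectoryRecord(i, stage, loss, {}, seq)

    def test_minimum_hard_record_selected(self):
        traj = [self.rec(1, "hard", 0.5, "AAA"), self.rec(2, "hard", 0.3, "BBB"
                .replace("B", "C")), self.rec(3, "hard", 0.4, "DDD")]
        seq, loss = select_best(traj)
        assert (seq, loss) == ("CCC", 0.3)

    def test_tie_goes_to_earliest(self):
        traj = [self.rec(1, "hard", 0.3, "AA"), self.rec(2, "hard", 0.3, "CC")]
        assert select_best(traj)[0] == "AA"

    def test_soft_records_ignored(self):
        traj = [self.rec(1, "soft", 0.0, "AA"), self.rec(2, "hard", 0.9, "CC")]
        assert select_best(traj) == ("CC", 0.9)

    def test_matches_linear_scan_oracle(self):
        rng = np.random.default_rng(0)
        losses = rng.uniform(size=10)
        traj = [self.rec(i + 1, "hard", l, f"S{i}".replace("S", "A"))
                for i, l in enumerate(losses)]
        seq, loss = select_best(traj)
        # independent brute-force scan
        best = min(range(10), key=lambda i: losses[i])
        assert loss == losses[best] and seq == traj[best].sequence

    def test_no_hard_records_raises(self):
        with pytest.raises(RuntimeError):
            select_best([self.rec(1, "soft", 0.1)])


# ---------------------------------------------------------------------------
# gradients
# ---------------------------------------------------------------------------

def finite_difference(loss_fn, logits, h=1e-6):
    grad = np.zeros_like(logits)
    for i in range(logits.shape[0]):
        for j in range(logits.shape[1]):
            up, down = logits.copy(), logits.copy()
            up[i, j] += h
            down[i, j] -= h
            grad[i, j] = (loss_fn(up) - loss_fn(down)) / (2 * h)
    return grad


@pytest.mark.parametrize("mean", ["arithmetic", "geometric"])
def test_solubility_gradient_matches_finite_differences(hydropathy, mean):
    rng = np.random.default_rng(7)
    logits = rng.normal(size=(5, 20))
    T = 0.8

    def loss_fn(z):
        return solubility_loss(SoftSequence(z, temperature=T), hydropathy, mean=mean)

    s = SoftSequence(logits, temperature=T)
    analytic = probs_grad_to_logits(s, solubility_loss_grad(s, hydropathy, mean=mean))
    numeric = finite_difference(loss_fn, logits)
    np.testing.assert_allclose(analytic, numeric, rtol=1e-5, atol=1e-10)


# ---------------------------------------------------------------------------
# the three-stage design loop
# ---------------------------------------------------------------------------

SHORT = StageSchedule(soft_iter=30, temp_iter=30, hard_iter=5)


class TestDesign3Stage:
    def test_run_is_deterministic(self, hydropathy):
        oracle = SurrogateOracle.for_length(13)
        w = LossWeights(solubility_weight=0.5)
        a = design_3stage(13, 1, SHORT, w, oracle, hydropathy)
        b = design_3stage(13, 1, SHORT, w, oracle, hydropathy)
        assert a.best_sequence == b.best_sequence
        assert [r.total_loss for r in a.trajectory] == [
            r.total_loss for r in b.trajectory
        ]

    def test_trajectory_structure(self, hydropathy):
        oracle = SurrogateOracle.for_length(6)
        res = design_3stage(6, 2, SHORT, LossWeights(), oracle, hydropathy)
        assert len(res.trajectory) == SHORT.total_iter
        stages = [r.stage for r in res.trajectory]
        assert stages == ["soft"] * 30 + ["temp"] * 30 + ["hard"] * 5
        assert [r.iteration for r in res.trajectory] == list(range(1, 66))
        assert len(res.best_sequence) == 6

    def test_solubility_only_recovers_closed_form_optimum(self, hydropathy):
        """With no oracle term the argmin of the loss is the R homopolymer."""
        w = LossWeights(solubility_weight=1.0, oracle_weights={})
        res = design_3stage(
            13, 4, StageSchedule(soft_iter=60, temp_iter=60, hard_iter=5), w,
            SurrogateOracle.for_length(13), hydropathy,
        )
        assert res.best_sequence == "R" * 13
        assert res.best_loss == pytest.approx(0.0, abs=1e-12)

    def test_best_is_minimum_of_hard_stage(self, hydropathy):
        oracle = SurrogateOracle.for_length(13)
        res = design_3stage(13, 9, SHORT, LossWeights(0.3), oracle, hydropathy)
        hard = [r for r in res.trajectory if r.stage == "hard"]
        assert res.best_loss == min(r.total_loss for r in hard)

    def test_non_finite_oracle_aborts_naming_iteration(self, hydropathy):
        def bad_oracle(s):
            return OracleOutput(
                losses={"interface": float("nan"), "confidence": 0.0},
                grads={"interface": np.zeros((13, 20)),
                       "confidence": np.zeros((13, 20))},
            )

        with pytest.raises(NonFiniteLossError, match="iteration 1"):
            design_3stage(13, 1, SHORT, LossWeights(), bad_oracle, hydropathy)
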