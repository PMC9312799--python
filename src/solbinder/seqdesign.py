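"""Gradient-based binder sequence design with a solubility loss.

The binder is represented as a *soft sequence*: a real-valued logits matrix
of shape (N positions x 20 residues) relaxed into per-position probability
distributions. Design runs in three stages:

1. **soft** — row-wise softmax at a fixed starting temperature;
2. **temp** — the temperature is annealed linearly towards a small value,
   sharpening the distributions;
3. **hard** — the forward pass uses the one-hot argmax of each row while
   gradients flow through the soft distribution (straight-through).

At every iteration the total loss is a weighted sum of the binding oracle's
confidence losses and the solubility loss

    L_sol(seq) = (1/N) * sum_i f(s_i)

where ``f`` is a normalized, loss-oriented amino-acid solubility index.
For a soft sequence the loss generalizes to the expectation
``(1/N) * sum_i sum_r p[i, r] * f(r)``, which coincides with the plain
lookup mean at one-hot and is linear (hence differentiable) in the
probabilities. The best sequence of a run is the decoded sequence of the
hard-stage iteration with the lowest total loss.

All losses here are linear in the probabilities, so gradients with respect
to the logits are obtained analytically through the softmax Jacobian; no
autograd framework is involved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np
from scipy.special import softmax

from .aaindex import ALPHABET, AA_TO_INDEX, IndexTable, TableStateError

N_RESIDUES = len(ALPHABET)

MODES = ("soft", "temp", "hard")


class NonFiniteLossError(RuntimeError):
    """The oracle (or a loss term) produced a non-finite value."""


# ---------------------------------------------------------------------------
# Soft sequence representation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SoftSequence:
    """A relaxed peptide: logits over the 20 canonical residues per position.

    ``probs`` is derived from the logits according to ``mode``:
    soft/temp -> row-wise ``softmax(logits / temperature)``; hard -> exact
    one-hot at each row's argmax (ties resolved to the alphabetically first
    residue, which is what ``argmax`` returns under the fixed alphabetical
    column order).
    """

    logits: np.ndarray
    temperature: float = 1.0
    mode: str = "soft"

    def __post_init__(self) -> None:
        logits = np.asarray(self.logits, dtype=float)
        if logits.ndim != 2 or logits.shape[1] != N_RESIDUES:
            raise ValueError(f"logits must be (N, 20), got {logits.shape}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if not (self.temperature > 0):
            raise ValueError("temperature must be positive")
        object.__setattr__(self, "logits", logits)

    @property
    def length(self) -> int:
        return self.logits.shape[0]

    @property
    def probs(self) -> np.ndarray:
        """Per-position residue distributions (rows sum to 1)."""
        if not np.all(np.isfinite(self.logits)):
            raise NonFiniteLossError("non-finite logits")
        if self.mode == "hard":
            onehot = np.zeros_like(self.logits)
            onehot[np.arange(self.length), np.argmax(self.logits, axis=1)] = 1.0
            return onehot
        return softmax(self.logits / self.temperature, axis=1)

    def soft_probs(self, temperature: float | None = None) -> np.ndarray:
        """Softmax distributions regardless of mode (straight-through backward)."""
        if not np.all(np.isfinite(self.logits)):
            raise NonFiniteLossError("non-finite logits")
        T = self.temperature if temperature is None else temperature
        return softmax(self.logits / T, axis=1)

    def decode(self) -> str:
        """Argmax residue string (alphabetical tie-break via column order)."""
        return "".join(ALPHABET[i] for i in np.argmax(self.logits, axis=1))


def init_logits(length: int, seed: int, temperature: float = 1.0) -> SoftSequence:
    """Seeded random initialization of the binder logits.

    Small Gaussian logits (sd 0.01) keep the initial distributions close to
    uniform, mirroring a random starting sequence while letting the loss
    signal rather than init noise decide near-ties during the anneal.
    Identical (length, seed) pairs give bitwise-identical logits.
    """
    if length < 1:
        raise ValueError(f"binder length must be >= 1, got {length}")
    rng = np.random.default_rng(seed)
    logits = 0.01 * rng.standard_normal((length, N_RESIDUES))
    return SoftSequence(logits=logits, temperature=temperature, mode="soft")


def to_probs(s: SoftSequence) -> np.ndarray:
    """Probability matrix of a soft sequence (see :class:`SoftSequence`)."""
    return s.probs


def one_hot(sequence: str) -> np.ndarray:
    """One-hot (N, 20) encoding of a residue string in alphabet order."""
    mat = np.zeros((len(sequence), N_RESIDUES))
    for i, aa in enumerate(sequence):
        try:
            mat[i, AA_TO_INDEX[aa]] = 1.0
        except KeyError:
            raise ValueError(
                f"non-canonical residue {aa!r} at position {i + 1}"
            ) from None
    return mat


def probs_grad_to_logits(
    s: SoftSequence, dprobs: np.ndarray, backward_temperature: float | None = None
) -> np.ndarray:
    """Chain a gradient w.r.t. probs through the (soft) softmax to the logits.

    In hard mode this is the straight-through estimator: the forward pass
    used the one-hot rows, the backward pass differentiates the softmax.
    """
    T = s.temperature if backward_temperature is None else backward_temperature
    P = s.soft_probs(T)
    inner = np.sum(dprobs * P, axis=1, keepdims=True)
    return P * (dprobs - inner) / T


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def solubility_loss(
    s: SoftSequence, table: IndexTable, mean: str = "arithmetic"
) -> float:
    """Expected normalized solubility-index value per position.

    The default arithmetic form is ``(1/N) * sum_i E_p[f]`` and lies in
    [0, 1]. ``mean="geometric"`` returns the geometric mean of the
    per-position expectations instead — provided for sensitivity checks
    only; the arithmetic form is the canonical loss.
    """
    f = _oriented_array(table)
    expect = s.probs @ f  # per-position expected index value
    if mean == "arithmetic":
        return float(expect.mean())
    if mean == "geometric":
        return float(np.exp(np.mean(np.log(np.maximum(expect, 1e-12)))))
    raise ValueError(f"mean must be 'arithmetic' or 'geometric', got {mean!r}")


def solubility_loss_grad(
    s: SoftSequence, table: IndexTable, mean: str = "arithmetic"
) -> np.ndarray:
    """Gradient of the solubility loss w.r.t. the probabilities."""
    f = _oriented_array(table)
    if mean == "arithmetic":
        return np.tile(f / s.length, (s.length, 1))
    if mean == "geometric":
        expect = np.maximum(s.probs @ f, 1e-12)
        g = float(np.exp(np.mean(np.log(expect))))
        return g / s.length * (1.0 / expect)[:, None] * f[None, :]
    raise ValueError(f"mean must be 'arithmetic' or 'geometric', got {mean!r}")


def _oriented_array(table: IndexTable) -> np.ndarray:
    if not table.is_normalized:
        raise TableStateError(
            f"index {table.name!r} must be normalized (and oriented) before "
            "use as a loss"
        )
    return table.as_array()


@dataclass(frozen=True)
class LossWeights:
    """Weights of the loss components.

    ``solubility_weight`` multiplies the solubility loss (the study sweeps
    0.0, 0.1, 0.3, 0.5, 0.7, 1.0); ``oracle_weights`` maps each oracle loss
    name to its weight.
    """

    solubility_weight: float = 0.0
    oracle_weights: Mapping[str, float] = field(
        default_factory=lambda: {"interface": 1.0, "confidence": 1.0}
    )

    def __post_init__(self) -> None:
        weights = [self.solubility_weight, *self.oracle_weights.values()]
        if not all(math.isfinite(w) and w >= 0 for w in weights):
            raise ValueError("all loss weights must be finite and >= 0")


def combined_loss(
    oracle_out, sol: float, w: LossWeights
) -> tuple[float, dict[str, float]]:
    """Weighted total loss plus the unweighted per-component breakdown."""
    components = {name: float(v) for name, v in oracle_out.losses.items()}
    components["solubility"] = float(sol)
    total = w.solubility_weight * sol
    for name, weight in w.oracle_weights.items():
        if name not in oracle_out.losses:
            raise KeyError(f"oracle did not report loss component {name!r}")
        total += weight * oracle_out.losses[name]
    if not math.isfinite(total):
        raise NonFiniteLossError("combined loss is non-finite")
    return float(total), components


# ---------------------------------------------------------------------------
# Three-stage optimization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StageSchedule:
    """Iteration counts and anneal/optimizer settings for the three stages.

    Defaults follow the standard protocol: 100 soft iterations, 100
    temperature-annealed iterations (linear, 1.0 -> 0.01), 10 hard
    (straight-through) iterations, plain normalized-gradient descent with a
    fixed step size of 0.1.
    """

    soft_iter: int = 100
    temp_iter: int = 100
    hard_iter: int = 10
    temp_start: float = 1.0
    temp_end: float = 0.01
    step_size: float = 0.1

    def __post_init__(self) -> None:
        if min(self.soft_iter, self.temp_iter, self.hard_iter) < 1:
            raise ValueError("all stage iteration counts must be >= 1")
        if not (0 < self.temp_end <= self.temp_start):
            raise ValueError("require 0 < temp_end <= temp_start")
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")

    @property
    def total_iter(self) -> int:
        return self.soft_iter + self.temp_iter + self.hard_iter


@dataclass(frozen=True)
class TrajectoryRecord:
    iteration: int          # 1-based, global across stages
    stage: str              # soft | temp | hard
    total_loss: float
    components: Mapping[str, float]
    sequence: str           # decoded (argmax) sequence at this iteration


@dataclass(frozen=True)
class DesignResult:
    """Outcome of one seeded design run."""

    trajectory: tuple[TrajectoryRecord, ...]
    best_sequence: str
    best_loss: float
    seed: int
    weights: LossWeights
    index_name: str

    @property
    def length(self) -> int:
        return len(self.best_sequence)


def select_best(trajectory: Iterable[TrajectoryRecord]) -> tuple[str, float]:
    """Best sequence: minimal total loss among hard-stage records.

    Ties go to the earliest iteration. Raises if the trajectory contains no
    hard-stage record.
    """
    best: TrajectoryRecord | None = None
    for rec in trajectory:
        if rec.stage != "hard":
            continue
        if best is None or rec.total_loss < best.total_loss:
            best = rec
    if best is None:
        raise RuntimeError("trajectory contains no hard-stage records")
    return best.sequence, best.total_loss


def _stage_plan(schedule: StageSchedule):
    """Yield (stage, mode, forward_temperature) per iteration."""
    for _ in range(schedule.soft_iter):
        yield "soft", "soft", schedule.temp_start
    for k in range(schedule.temp_iter):
        frac = (k + 1) / schedule.temp_iter
        T = schedule.temp_start + (schedule.temp_end - schedule.temp_start) * frac
        yield "temp", "temp", T
    for _ in range(schedule.hard_iter):
        yield "hard", "hard", schedule.temp_end


def design_3stage(
    length: int,
    seed: int,
    schedule: StageSchedule,
    weights: LossWeights,
    oracle: Callable[[SoftSequence], "OracleOutput"],
    table: IndexTable,
    mean: str = "arithmetic",
) -> DesignResult:
    """Run the soft -> annealed -> hard design loop for one seed.

    ``oracle`` is any callable mapping a :class:`SoftSequence` to an
    :class:`~solbinder.surrogate.OracleOutput` with gradients w.r.t. the
    probabilities. The optimizer is plain gradient descent on the logits
    with per-iteration global L2 gradient normalization and a fixed step
    size; in the hard stage gradients are straight-through and evaluated at
    unit backward temperature so they stay informative once the anneal has
    saturated the softmax.
    """
    z = init_logits(length, seed, schedule.temp_start).logits.copy()
    records: list[TrajectoryRecord] = []

    for iteration, (stage, mode, T) in enumerate(_stage_plan(schedule), start=1):
        s = SoftSequence(logits=z, temperature=T, mode=mode)
        out = oracle(s)
        if not all(math.isfinite(v) for v in out.losses.values()):
            raise NonFiniteLossError(
                f"oracle returned a non-finite loss at iteration {iteration} "
                f"({stage} stage): {dict(out.losses)}"
            )
        sol = solubility_loss(s, table, mean=mean)
        total, components = combined_loss(out, sol, weights)
        records.append(
            TrajectoryRecord(
                iteration=iteration, stage=stage, total_loss=total,
                components=components, sequence=s.decode(),
            )
        )

        dprobs = weights.solubility_weight * solubility_loss_grad(s, table, mean=mean)
        for name, weight in weights.oracle_weights.items():
            if weight != 0.0:
                dprobs = dprobs + weight * out.grads[name]
        backward_T = 1.0 if mode == "hard" else None
        dz = probs_grad_to_logits(s, dprobs, backward_temperature=backward_T)
        norm = np.linalg.norm(dz)
        if norm > 0:
            z = z - schedule.step_size * dz / norm

    best_sequence, best_loss = select_best(records)
    return DesignResult(
        trajectory=tuple(records), best_sequence=best_sequence,
        best_loss=best_loss, seed=seed, weights=weights, index_name=table.name,
    )
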