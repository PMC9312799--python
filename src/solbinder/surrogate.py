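"""Binding-oracle contract and a deterministic differentiable surrogate.

A *binding oracle* is any callable ``SoftSequence -> OracleOutput`` whose
named scalar losses (e.g. a structure-prediction confidence loss and an
inter-chain placement loss) are bounded below by 0 and come with gradients
with respect to the per-position probabilities. A structure-predictor-backed
adapter can implement this contract externally; this module ships a
self-contained surrogate so the full design loop runs at desk scale.

The surrogate scores a sequence against a fixed *interface profile*: an
(N x 20) matrix of per-position residue favourabilities in [0, 1]. Its
``interface`` loss is ``1 - mean position-wise expected favourability``. The
default profile rewards the aromatic/hydrophobic residues W, Y, F and L in a
central core (positions 4-11) and penalizes hydrophilic residues there,
emulating the empirical tendency of unconstrained binder hallucination to
pack hydrophobic and aromatic residues into the binding interface. Because
those residues score poorly on the solubility indices, the surrogate loss
and the solubility loss are in deliberate tension, giving the solubility
weight a genuine trade-off to control.

A constant-zero ``confidence`` loss is also reported so that multi-component
loss weighting is exercised end-to-end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .aaindex import ALPHABET, AA_TO_INDEX, AROMATIC_HYDROPHOBIC, HYDROPHILIC
from .seqdesign import N_RESIDUES, SoftSequence

CORE_START = 4   # 1-based first core position
CORE_END = 11    # 1-based last core position (inclusive)


@dataclass(frozen=True)
class OracleOutput:
    """Named scalar losses plus gradients w.r.t. the probability matrix."""

    losses: Mapping[str, float]
    grads: Mapping[str, np.ndarray] = field(default_factory=dict)

    @property
    def has_grads(self) -> bool:
        return set(self.grads) >= set(self.losses)


@dataclass(frozen=True)
class InterfaceProfile:
    """Per-position residue favourability matrix (N x 20, values in [0, 1])."""

    preference: np.ndarray

    def __post_init__(self) -> None:
        pref = np.asarray(self.preference, dtype=float)
        if pref.ndim != 2 or pref.shape[1] != N_RESIDUES:
            raise ValueError(f"preference must be (N, 20), got {pref.shape}")
        if pref.min() < 0 or pref.max() > 1:
            raise ValueError("preference values must lie in [0, 1]")
        if not np.allclose(pref.max(axis=1), 1.0):
            raise ValueError("every profile row must attain a maximum of 1.0")
        object.__setattr__(self, "preference", pref)

    @property
    def length(self) -> int:
        return self.preference.shape[0]

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.preference, columns=list(ALPHABET),
            index=pd.RangeIndex(1, self.length + 1, name="position"),
        )
        df.to_csv(path, sep="\t", float_format="%.6g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "InterfaceProfile":
        df = pd.read_csv(path, sep="\t", index_col="position")
        return cls(preference=df[list(ALPHABET)].to_numpy(dtype=float))


def default_profile(length: int) -> InterfaceProfile:
    """Deterministic hydrophobic-core profile for a binder of given length.

    Core rows (positions 4 to min(11, N), 1-based) give preference 1.0 to
    W/Y/F/L, 0.1 to the hydrophilic residues R/K/D/E/N/Q and 0.3 to the
    rest. Flanking rows are flatter (0.8 everywhere except 1.0 on W/Y/F/L),
    so they cost little to repurpose when other losses pull on them.
    """
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    pref = np.full((length, N_RESIDUES), 0.8)
    core = slice(CORE_START - 1, min(CORE_END, length))
    pref[core, :] = 0.3
    for aa in HYDROPHILIC:
        pref[core, AA_TO_INDEX[aa]] = 0.1
    for aa in AROMATIC_HYDROPHOBIC:
        pref[:, AA_TO_INDEX[aa]] = 1.0
    return InterfaceProfile(preference=pref)


def surrogate_evaluate(s: SoftSequence, profile: InterfaceProfile) -> OracleOutput:
    """Score a soft sequence against an interface profile.

    ``interface`` loss = 1 - (1/N) sum_i sum_r probs[i, r] * preference[i, r];
    linear in the probabilities, value in [0, 1], deterministic. The
    ``confidence`` loss is fixed at 0 with a zero gradient.
    """
    if profile.length != s.length:
        raise ValueError(
            f"profile length {profile.length} does not match sequence "
            f"length {s.length}"
        )
    pref = profile.preference
    interface = 1.0 - float(np.sum(s.probs * pref)) / s.length
    return OracleOutput(
        losses={"interface": interface, "confidence": 0.0},
        grads={
            "interface": -pref / s.length,
            "confidence": np.zeros_like(pref),
        },
    )


class SurrogateOracle:
    """Callable oracle wrapping a fixed :class:`InterfaceProfile`."""

    def __init__(self, profile: InterfaceProfile):
        self.profile = profile

    @classmethod
    def for_length(cls, length: int) -> "SurrogateOracle":
        return cls(default_profile(length))

    def __call__(self, s: SoftSequence) -> OracleOutput:
        return surrogate_evaluate(s, self.profile)
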