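"""Evaluation harness: baselines, scoring, filtering, and logo matrices.

Mirrors the downstream analysis of a design campaign: score sequences with
a normalized solubility index, generate random and single-substitution
baseline sets, apply the dual-threshold filter (solubility strictly above a
reference peptide's logS, docking affinity strictly below — i.e. stronger
than — the reference's binding free energy), and build position frequency
matrices for sequence-logo rendering.

External scores (logS from a solubility predictor, binding free energies
from a docking tool) are ingested from CSV; when absent, the internal index
mean serves as the solubility score and affinity filtering is unavailable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .aaindex import (
    ALPHABET,
    AA_TO_INDEX,
    AROMATIC_HYDROPHOBIC,
    HYDROPHILIC,
    IndexTable,
    validate_sequence,
)

ORIGINS = ("designed", "random", "substitution", "reference")

#: Reference thresholds from the MDM2 system: logS and docking binding free
#: energy of the PDIQ+'N' peptide (the high-affinity engineered p53 variant
#: extended to 13 residues). A candidate passes only if it beats both.
PDIQ_N_LOGS = 0.4420
PDIQ_N_AFFINITY = -22.5

#: The p53 transactivation peptide, the native MDM2 binder.
P53_PEPTIDE = "ETFSDLWKLLPEN"


@dataclass
class CandidateRecord:
    """One designed or baseline sequence with its scores and filter verdict."""

    sequence: str
    origin: str = "designed"
    seed: int | None = None
    weight: float | None = None
    index_name: str | None = None
    solubility_score: float | None = None
    affinity_score: float | None = None
    passed_filter: bool | None = None

    def __post_init__(self) -> None:
        validate_sequence(self.sequence, context=f"candidate {self.origin}")
        if self.origin not in ORIGINS:
            raise ValueError(f"origin must be one of {ORIGINS}, got {self.origin!r}")


def score_sequence(sequence: str, table: IndexTable) -> float:
    """Mean normalized, loss-oriented index value over the residues.

    Identical to the design engine's solubility loss evaluated at the
    one-hot encoding of ``sequence``.
    """
    validate_sequence(sequence)
    return float(np.mean([table.value(aa) for aa in sequence]))


def hydrophilic_fraction(sequence: str) -> float:
    """Fraction of residues in the hydrophilic class {R, K, D, E, N, Q}."""
    validate_sequence(sequence)
    return sum(aa in HYDROPHILIC for aa in sequence) / len(sequence)


def aromatic_hydrophobic_fraction(sequence: str) -> float:
    """Fraction of residues in {W, Y, F, L}, the interface-favoured class."""
    validate_sequence(sequence)
    return sum(aa in AROMATIC_HYDROPHOBIC for aa in sequence) / len(sequence)


# ---------------------------------------------------------------------------
# Baseline generators
# ---------------------------------------------------------------------------

def gen_random_sequences(n: int, length: int, seed: int) -> list[CandidateRecord]:
    """``n`` uniform random sequences of the given length (seeded)."""
    if n < 1 or length < 1:
        raise ValueError("n and length must both be >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, len(ALPHABET), size=(n, length))
    return [
        CandidateRecord(
            sequence="".join(ALPHABET[i] for i in row), origin="random", seed=seed
        )
        for row in draws
    ]


def gen_single_substitutions(reference: str) -> list[CandidateRecord]:
    """Every sequence exactly one substitution away from ``reference``.

    All 19 alternative residues at every position: 19 * len(reference)
    variants, no duplicates, the reference itself excluded.
    """
    validate_sequence(reference, context="reference")
    records = []
    for pos, original in enumerate(reference):
        for aa in ALPHABET:
            if aa == original:
                continue
            variant = reference[:pos] + aa + reference[pos + 1:]
            records.append(CandidateRecord(sequence=variant, origin="substitution"))
    return records


# ---------------------------------------------------------------------------
# Dual-threshold filtering
# ---------------------------------------------------------------------------

def filter_candidates(
    records: Sequence[CandidateRecord],
    sol_threshold: float = PDIQ_N_LOGS,
    aff_threshold: float = PDIQ_N_AFFINITY,
) -> list[CandidateRecord]:
    """Keep candidates strictly better than both thresholds.

    A record passes iff ``solubility_score > sol_threshold`` and
    ``affinity_score < aff_threshold`` (affinities are binding free
    energies: lower / more negative = stronger binding). Comparisons are
    strict, so a record exactly at a threshold fails. ``passed_filter`` is
    set on every input record; survivors are returned in input order.
    """
    for k, rec in enumerate(records):
        if rec.solubility_score is None or rec.affinity_score is None:
            raise ValueError(
                f"record {k} ({rec.sequence}): both solubility_score and "
                "affinity_score must be set before filtering"
            )
    survivors = []
    for rec in records:
        rec.passed_filter = (
            rec.solubility_score > sol_threshold
            and rec.affinity_score < aff_threshold
        )
        if rec.passed_filter:
            survivors.append(rec)
    return survivors


# ---------------------------------------------------------------------------
# Position frequency matrices (sequence logos)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Residue counts and frequencies per binder position (N x 20)."""

    counts: np.ndarray
    frequencies: np.ndarray
    n_sequences: int

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    def to_dataframe(self, kind: str = "frequencies") -> pd.DataFrame:
        mat = self.frequencies if kind == "frequencies" else self.counts
        return pd.DataFrame(
            mat, columns=list(ALPHABET),
            index=pd.RangeIndex(1, self.length + 1, name="position"),
        )

    def to_csv(self, path: str | Path, kind: str = "frequencies") -> None:
        self.to_dataframe(kind).to_csv(path)


def build_pfm(sequences: Sequence[str]) -> PositionFrequencyMatrix:
    """Count residues per position over equal-length canonical sequences."""
    if not sequences:
        raise ValueError("need at least one sequence")
    length = len(sequences[0])
    counts = np.zeros((length, len(ALPHABET)), dtype=int)
    for seq in sequences:
        validate_sequence(seq)
        if len(seq) != length:
            raise ValueError(
                f"ragged input: expected length {length}, got {len(seq)} "
                f"for {seq!r}"
            )
        for i, aa in enumerate(seq):
            counts[i, AA_TO_INDEX[aa]] += 1
    return PositionFrequencyMatrix(
        counts=counts, frequencies=counts / len(sequences),
        n_sequences=len(sequences),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "sequence", "origin", "seed", "weight", "index_name",
    "solubility_score", "affinity_score", "passed_filter",
]


def write_candidates_csv(records: Iterable[CandidateRecord], path: str | Path) -> None:
    df = pd.DataFrame([{c: getattr(r, c) for c in _CSV_COLUMNS} for r in records])
    df.to_csv(path, index=False)


def read_candidates_csv(path: str | Path) -> list[CandidateRecord]:
    """Load candidates from CSV (external scores allowed; extra columns ignored)."""
    df = pd.read_csv(path)
    records = []
    for row in df.itertuples(index=False):
        kwargs = {}
        for col in _CSV_COLUMNS:
            if hasattr(row, col):
                value = getattr(row, col)
                kwargs[col] = None if pd.isna(value) else value
        if kwargs.get("seed") is not None:
            kwargs["seed"] = int(kwargs["seed"])
        if kwargs.get("passed_filter") is not None:
            kwargs["passed_filter"] = bool(kwargs["passed_filter"])
        records.append(CandidateRecord(**kwargs))
    return records


def write_fasta(records: Iterable[CandidateRecord], path: str | Path) -> None:
    seq_records = []
    for k, rec in enumerate(records):
        bits = [rec.origin]
        if rec.seed is not None:
            bits.append(f"seed{rec.seed}")
        if rec.weight is not None:
            bits.append(f"w{rec.weight:g}")
        if rec.index_name:
            bits.append(rec.index_name)
        seq_records.append(
            SeqRecord(Seq(rec.sequence), id="_".join(bits) + f"_{k}", description="")
        )
    SeqIO.write(seq_records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[str]:
    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
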