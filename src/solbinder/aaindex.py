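"""Amino-acid solubility index tables.

Three per-residue scales are bundled with the package:

``hydrophobicity``
    Argos et al. (1982) membrane-buried-region hydrophobicity scale. High
    values mark strongly hydrophobic residues.
``hydropathy``
    Kyte & Doolittle (1982) hydropathy scale. High values mark strongly
    hydrophobic residues.
``swi``
    Solubility-Weighted Index per-residue weights (Bhandari et al. 2020).
    High values *favour* solubility, so this scale is inverted after
    normalization.

Each table is min-max normalized to [0, 1] and oriented so that **larger
values are worse for solubility**, making the normalized value directly
usable as a per-residue loss contribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np

#: The 20 canonical residues, one-letter codes, alphabetical. This ordering is
#: used everywhere in the package: logits columns, PFM rows, table arrays.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_TO_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
CANONICAL = frozenset(ALPHABET)

#: Hydrophilic residue class used for composition summaries.
HYDROPHILIC = frozenset("RKDENQ")
#: Hydrophobic/aromatic residues favoured at protein-protein interfaces.
AROMATIC_HYDROPHOBIC = frozenset("WYFL")

#: Bundled scales and whether loss orientation requires inversion.
BUNDLED_INDICES = {
    "hydrophobicity": ("hydrophobicity.tsv", False),
    "hydropathy": ("hydropathy.tsv", False),
    "swi": ("swi.tsv", True),
}


class MalformedTableError(ValueError):
    """An index file violates the 20-canonical-residue table contract."""


class DegenerateRangeError(ValueError):
    """All raw values identical; min-max normalization is undefined."""


class TableStateError(RuntimeError):
    """Operation requires a normalized table but got a raw one."""


@dataclass(frozen=True)
class IndexTable:
    """One solubility scale: raw values plus optional normalized/oriented form.

    Parameters
    ----------
    name
        Identifier of the scale (e.g. ``"hydropathy"``).
    raw
        Mapping residue one-letter code -> raw published value; exactly the
        20 canonical residues.
    normalized
        Mapping residue -> value in [0, 1]; empty until
        :func:`normalize_index` has been applied.
    loss_oriented
        True when inversion (``1 - x``) was applied after normalization,
        i.e. for SWI-type scales where the raw value favours solubility.
    """

    name: str
    raw: Mapping[str, float]
    normalized: Mapping[str, float] = field(default_factory=dict)
    loss_oriented: bool = False

    def __post_init__(self) -> None:
        _check_keys(self.raw, self.name)
        if self.normalized:
            _check_keys(self.normalized, self.name)

    @property
    def is_normalized(self) -> bool:
        return bool(self.normalized)

    def value(self, residue: str) -> float:
        """Normalized, loss-oriented value of one residue."""
        if not self.is_normalized:
            raise TableStateError(f"index {self.name!r} is not normalized")
        if residue not in CANONICAL:
            raise MalformedTableError(
                f"non-canonical residue {residue!r} for index {self.name!r}"
            )
        return self.normalized[residue]

    def as_array(self) -> np.ndarray:
        """Normalized values as a length-20 vector in ``ALPHABET`` order."""
        if not self.is_normalized:
            raise TableStateError(f"index {self.name!r} is not normalized")
        return np.array([self.normalized[aa] for aa in ALPHABET], dtype=float)


def _check_keys(values: Mapping[str, float], name: str) -> None:
    keys = set(values)
    if keys != CANONICAL:
        missing = sorted(CANONICAL - keys)
        extra = sorted(keys - CANONICAL)
        raise MalformedTableError(
            f"index {name!r} must cover exactly the 20 canonical residues; "
            f"missing={missing} unexpected={extra}"
        )


def load_index(name: str, source: str | Path | None = None) -> IndexTable:
    """Load one raw index table from a two-column delimited file.

    ``source=None`` loads the bundled file registered under ``name``. The
    returned table is raw-only; run :func:`normalize_index` to obtain the
    [0, 1] loss-oriented form.
    """
    if source is None:
        try:
            fname, _ = BUNDLED_INDICES[name]
        except KeyError:
            raise KeyError(
                f"unknown bundled index {name!r}; choose from "
                f"{sorted(BUNDLED_INDICES)}"
            ) from None
        text = resources.files("solbinder.data").joinpath(fname).read_text()
    else:
        text = Path(source).read_text()

    raw: dict[str, float] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", "\t").split()
        if len(parts) != 2:
            raise MalformedTableError(
                f"index {name!r} line {lineno}: expected two columns, got {line!r}"
            )
        residue, value = parts
        if residue not in CANONICAL:
            raise MalformedTableError(
                f"index {name!r} line {lineno}: unknown residue code {residue!r}"
            )
        if residue in raw:
            raise MalformedTableError(
                f"index {name!r} line {lineno}: duplicate residue {residue!r}"
            )
        try:
            raw[residue] = float(value)
        except ValueError:
            raise MalformedTableError(
                f"index {name!r} line {lineno}: non-numeric value {value!r}"
            ) from None
    _check_keys(raw, name)
    return IndexTable(name=name, raw=raw)


def normalize_index(table: IndexTable, invert: bool = False) -> IndexTable:
    """Min-max normalize a raw table to [0, 1]; optionally invert (``1 - x``).

    Inversion orients solubility-favouring scales (SWI) so that, like the
    hydrophobicity scales, larger normalized values mean worse solubility.
    Returns a new table; the input is unmodified.
    """
    values = np.array([table.raw[aa] for aa in ALPHABET], dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        raise DegenerateRangeError(
            f"index {table.name!r}: all raw values identical ({lo}); "
            "min-max normalization undefined"
        )
    norm = (values - lo) / (hi - lo)
    if invert:
        norm = 1.0 - norm
    normalized = {aa: float(v) for aa, v in zip(ALPHABET, norm)}
    return IndexTable(
        name=table.name, raw=dict(table.raw), normalized=normalized,
        loss_oriented=invert,
    )


def oriented_index(name: str, source: str | Path | None = None) -> IndexTable:
    """Load and orient a bundled index in one step.

    Applies the inversion registered for the scale (currently only SWI), so
    that the result is directly usable as a loss table.
    """
    table = load_index(name, source)
    invert = BUNDLED_INDICES.get(name, (None, False))[1]
    return normalize_index(table, invert=invert)


def validate_sequence(sequence: str, context: str = "sequence") -> str:
    """Reject sequences containing non-canonical residues, naming the position."""
    for pos, aa in enumerate(sequence, start=1):
        if aa not in CANONICAL:
            raise ValueError(
                f"{context}: non-canonical residue {aa!r} at position {pos}"
            )
    return sequence
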