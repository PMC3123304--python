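"""HLA binding prediction with multiplicative per-position coefficients.

The predicted half-time of dissociation of a peptide from an HLA molecule
(T1/2, seconds) is an allele-specific constant times the product of one
coefficient per peptide position, looked up by the residue at that position
(the Parker/BIMAS scheme). Coefficient tables are allele- and
length-specific; the original published tables are not redistributed here —
a file format and loader accept user-supplied tables, and seeded synthetic
tables (see :mod:`mihakit.simulate`) serve testing.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .variants import STANDARD_AA, AllelicPeptidePair

_AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}

POLICIES = ("alt_only", "either", "both")


@dataclass(frozen=True)
class CoefficientTable:
    """Per-position amino-acid coefficients plus an allele constant (seconds).

    ``coefficients`` is a (length, 20) array; column order follows
    :data:`mihakit.variants.STANDARD_AA`.
    """

    allele: str
    length: int
    coefficients: np.ndarray = field(repr=False)
    constant: float = 1.0

    def __post_init__(self) -> None:
        coeff = np.asarray(self.coefficients, dtype=float)
        if coeff.shape != (self.length, 20):
            raise ValueError(
                f"coefficient matrix must be ({self.length}, 20), got {coeff.shape}"
            )
        if (coeff < 0).any():
            raise ValueError("coefficients must be non-negative")
        if not self.constant > 0:
            raise ValueError(f"allele constant must be positive, got {self.constant}")
        object.__setattr__(self, "coefficients", coeff)

    def coefficient(self, position: int, aa: str) -> float:
        """Coefficient at 1-based ``position`` for residue ``aa``."""
        return float(self.coefficients[position - 1, _AA_INDEX[aa]])


@dataclass(frozen=True)
class BindingPrediction:
    peptide: str
    t_half_seconds: float


@dataclass(frozen=True)
class ScoredPair:
    """An allelic peptide pair with both allelic T1/2 scores attached."""

    pair: AllelicPeptidePair
    ref_t_half: float
    alt_t_half: float


def score_t_half(peptide: str, table: CoefficientTable) -> BindingPrediction:
    """Predict the dissociation half-time of ``peptide`` from ``table``'s allele.

    T1/2 = constant × Π_i coefficient(i, peptide[i]).
    """
    if len(peptide) != table.length:
        raise ValueError(
            f"peptide {peptide!r} has length {len(peptide)}; table "
            f"{table.allele} covers length {table.length}"
        )
    try:
        idx = [_AA_INDEX[aa] for aa in peptide]
    except KeyError as exc:
        raise ValueError(f"peptide {peptide!r} contains unknown residue {exc.args[0]!r}")
    product = float(np.prod(table.coefficients[np.arange(table.length), idx]))
    return BindingPrediction(peptide=peptide, t_half_seconds=table.constant * product)


def filter_binders(
    pairs: Iterable[AllelicPeptidePair],
    tables: CoefficientTable | Mapping[int, CoefficientTable] | Sequence[CoefficientTable],
    min_t_half: float = 30.0,
    policy: str = "alt_only",
) -> list[ScoredPair]:
    """Score allelic pairs and retain those meeting the T1/2 threshold.

    The threshold is inclusive (a predicted half-time exactly at the minimum
    is retained). ``policy`` decides which allelic peptide must bind:

    * ``alt_only`` — the MiHA-positive (alternate) peptide (default),
    * ``either`` — at least one of the two allelic peptides,
    * ``both`` — both allelic peptides.

    ``tables`` may be a single table, a mapping length → table, or a
    sequence of tables (keyed by their lengths); each pair is scored
    against the table of its own length.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    if min_t_half < 0:
        raise ValueError(f"min_t_half must be non-negative, got {min_t_half}")
    if isinstance(tables, CoefficientTable):
        by_length = {tables.length: tables}
    elif isinstance(tables, Mapping):
        by_length = dict(tables)
    else:
        by_length = {t.length: t for t in tables}

    pairs = list(pairs)
    missing = sorted({p.length for p in pairs} - set(by_length))
    if missing:
        raise ValueError(f"no coefficient table for peptide length(s): {missing}")

    retained: list[ScoredPair] = []
    for p in pairs:
        table = by_length[p.length]
        ref_t = score_t_half(p.ref_peptide, table).t_half_seconds
        alt_t = score_t_half(p.alt_peptide, table).t_half_seconds
        if policy == "alt_only":
            keep = alt_t >= min_t_half
        elif policy == "either":
            keep = alt_t >= min_t_half or ref_t >= min_t_half
        else:  # both
            keep = alt_t >= min_t_half and ref_t >= min_t_half
        if keep:
            retained.append(ScoredPair(pair=p, ref_t_half=ref_t, alt_t_half=alt_t))
    return retained


# ---------------------------------------------------------------------------
# Coefficient table file format
#
#   #allele=<name> length=<L> constant=<float>
#   pos <tab> A <tab> C <tab> ... (20 amino-acid columns, alphabetical)
#   1   <c> ...
#
# Floats are written with repr() so that read(write(t)) is bit-exact.

_HEADER_RE = re.compile(r"^#allele=(\S+)\s+length=(\d+)\s+constant=(\S+)\s*$")


def write_coefficient_table(table: CoefficientTable, path: str | Path) -> None:
    lines = [f"#allele={table.allele} length={table.length} constant={table.constant!r}"]
    lines.append("pos\t" + "\t".join(STANDARD_AA))
    for i in range(table.length):
        row = "\t".join(repr(float(v)) for v in table.coefficients[i])
        lines.append(f"{i + 1}\t{row}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_coefficient_table(path: str | Path) -> CoefficientTable:
    text = Path(path).read_text().splitlines()
    m = _HEADER_RE.match(text[0])
    if not m:
        raise ValueError(f"{path}: missing '#allele=... length=... constant=...' header")
    allele, length, constant = m.group(1), int(m.group(2)), float(m.group(3))
    header = text[1].split("\t")
    if header[0] != "pos" or "".join(header[1:]) != STANDARD_AA:
        raise ValueError(f"{path}: column header must be 'pos' + the 20 amino acids")
    coeff = np.empty((length, 20), dtype=float)
    for line in text[2 : 2 + length]:
        fields = line.split("\t")
        pos = int(fields[0])
        coeff[pos - 1] = [float(v) for v in fields[1:21]]
    return CoefficientTable(allele=allele, length=length, coefficients=coeff,
                            constant=constant)


def log_t_half(peptide: str, table: CoefficientTable) -> float:
    """log(T1/2) as a sum of logs; requires strictly positive coefficients."""
    total = math.log(table.constant)
    for i, aa in enumerate(peptide):
        total += math.log(table.coefficient(i + 1, aa))
    return total
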