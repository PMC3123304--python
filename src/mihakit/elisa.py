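"""Affinity classification of UV-exchange ELISA optical densities.

After UV-mediated peptide exchange into HLA-A2 monomers, a
streptavidin-sandwich ELISA absorbance (OD at 414 nm, mean of triplicates)
reports how stably each peptide holds the complex together. ODs are
classified low / intermediate / high; low binders are discarded before
multimerization.

Boundary convention: low is od < 0.4; 0.4 itself is intermediate; high is
od >= 1.25. (Published descriptions of the low/intermediate boundary vary
between "OD <= 0.39" and "OD <= 0.4"; this package fixes 0.4 as
intermediate so the retained set is the union of intermediate and high.)
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd


class AffinityClass(str, enum.Enum):
    LOW = "low"
    INTERMEDIATE = "intermediate"
    HIGH = "high"


@dataclass(frozen=True)
class ODRecord:
    peptide: str
    od: float
    affinity_class: AffinityClass | None = None


@dataclass(frozen=True)
class TriageResult:
    retained: tuple[ODRecord, ...]
    discarded: tuple[ODRecord, ...]
    counts: dict  # AffinityClass -> int

    @property
    def n_total(self) -> int:
        return len(self.retained) + len(self.discarded)


def classify_od(od: float, low_cut: float = 0.4, high_cut: float = 1.25) -> AffinityClass:
    """Classify one OD reading into low / intermediate / high affinity."""
    if od < 0:
        raise ValueError(f"OD must be non-negative, got {od}")
    if not 0 < low_cut < high_cut:
        raise ValueError(f"need 0 < low_cut < high_cut, got {low_cut}, {high_cut}")
    if od < low_cut:
        return AffinityClass.LOW
    if od < high_cut:
        return AffinityClass.INTERMEDIATE
    return AffinityClass.HIGH


def triage(
    records: Iterable[ODRecord],
    low_cut: float = 0.4,
    high_cut: float = 1.25,
) -> TriageResult:
    """Partition OD records by affinity class; keep intermediate + high.

    Low-affinity peptides do not form stable complexes and are dropped from
    multimer production; intermediate and high binders proceed.
    """
    retained: list[ODRecord] = []
    discarded: list[ODRecord] = []
    counts = {cls: 0 for cls in AffinityClass}
    for rec in records:
        cls = classify_od(rec.od, low_cut=low_cut, high_cut=high_cut)
        rec = ODRecord(peptide=rec.peptide, od=rec.od, affinity_class=cls)
        counts[cls] += 1
        (discarded if cls is AffinityClass.LOW else retained).append(rec)
    return TriageResult(retained=tuple(retained), discarded=tuple(discarded),
                        counts=counts)


def read_od_table(path: str | Path, sep: str = "\t") -> list[ODRecord]:
    """Read a delimited OD table.

    Accepts either a pre-averaged ``od`` column or triplicate columns
    ``od_rep1..od_rep3`` (averaged on load).
    """
    df = pd.read_csv(path, sep=sep)
    if "peptide" not in df.columns:
        raise ValueError("OD table must have a 'peptide' column")
    if "od" in df.columns:
        od = df["od"].astype(float)
    else:
        reps = [c for c in ("od_rep1", "od_rep2", "od_rep3") if c in df.columns]
        if not reps:
            raise ValueError("OD table needs an 'od' column or od_rep1..3 columns")
        od = df[reps].astype(float).mean(axis=1)
    return [ODRecord(peptide=str(p), od=float(v)) for p, v in zip(df["peptide"], od)]


def triage_to_frame(result: TriageResult) -> pd.DataFrame:
    rows = [
        {"peptide": r.peptide, "od": r.od, "affinity_class": r.affinity_class.value,
         "retained": r.affinity_class is not AffinityClass.LOW}
        for r in result.retained + result.discarded
    ]
    return pd.DataFrame(rows, columns=["peptide", "od", "affinity_class", "retained"])
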