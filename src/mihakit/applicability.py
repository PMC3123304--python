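"""Hardy-Weinberg donor-recipient disparity probability and frequency filtering.

A MiHA is clinically exploitable in a transplant pair when the recipient
carries at least one MiHA-positive allele (the antigen is presented) while
the HLA-matched unrelated donor carries none (donor T cells are not
tolerant). Under Hardy-Weinberg proportions with MiHA-positive allele
frequency p (q = 1 - p) and donor/recipient independence, this
"theoretical clinical applicability" is

    A(p) = (1 - q^2) * q^2

which is at most 0.25 (at q^2 = 1/2, i.e. p = 1 - sqrt(1/2) ≈ 0.293).
Requiring A(p) >= 0.20 selects allele frequencies in roughly the 15-46%
band used operationally to shortlist candidates.

Caveat: related-donor transplants violate the independence assumption; the
formula describes the HLA-matched *unrelated* donor setting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .binding import ScoredPair

#: The operational allele-frequency band (inclusive). The exact solution of
#: A(p) >= 0.20 is (0.1494, 0.4743); the rounded band is what candidate
#: shortlisting conventionally uses.
DEFAULT_BAND = (0.15, 0.46)

MAX_APPLICABILITY = 0.25


@dataclass(frozen=True)
class ApplicabilityResult:
    allele_freq: float
    applicability: float

    #: Stated model assumptions, carried into output metadata.
    assumptions = (
        "Hardy-Weinberg genotype proportions",
        "donor and recipient genotypes independent (HLA-matched unrelated donor)",
    )


@dataclass(frozen=True)
class GenotypePair:
    """Donor/recipient genotypes at one SNP as MiHA-positive allele counts."""

    snp_id: str
    recipient_alt_count: int
    donor_alt_count: int

    def validate(self) -> None:
        for label, count in (("recipient", self.recipient_alt_count),
                             ("donor", self.donor_alt_count)):
            if count not in (0, 1, 2):
                raise ValueError(
                    f"{self.snp_id}: {label} allele count must be 0, 1 or 2, got {count}"
                )


def clinical_applicability(p: float) -> ApplicabilityResult:
    """Probability that a random unrelated pair is disparate in the GVT direction.

    P(recipient carries >= 1 MiHA-positive allele) * P(donor carries none)
    = (1 - (1-p)^2) * (1-p)^2 under HWE.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"allele frequency must be in [0, 1], got {p}")
    q2 = (1.0 - p) ** 2
    return ApplicabilityResult(allele_freq=p, applicability=(1.0 - q2) * q2)


def frequency_band(threshold: float) -> tuple[float, float]:
    """Exact allele-frequency interval where applicability >= ``threshold``.

    With x = (1-p)^2 the condition (1-x)x >= t reads x^2 - x + t <= 0,
    whose roots are x = (1 ± sqrt(1-4t)) / 2; translating back through
    p = 1 - sqrt(x) gives the closed-form band. No band exists above the
    maximum applicability of 0.25.
    """
    if not 0.0 < threshold < MAX_APPLICABILITY:
        raise ValueError(
            f"threshold must be in (0, {MAX_APPLICABILITY}); got {threshold} "
            "(applicability never exceeds 0.25)"
        )
    disc = math.sqrt(1.0 - 4.0 * threshold)
    x_lo, x_hi = (1.0 - disc) / 2.0, (1.0 + disc) / 2.0
    return (1.0 - math.sqrt(x_hi), 1.0 - math.sqrt(x_lo))


def filter_by_frequency(
    pairs: Iterable[ScoredPair],
    band: Sequence[float] = DEFAULT_BAND,
) -> list[ScoredPair]:
    """Retain scored pairs whose MiHA-positive allele frequency lies in ``band``.

    Both band edges are inclusive.
    """
    low, high = float(band[0]), float(band[1])
    if not 0.0 <= low <= high <= 1.0:
        raise ValueError(f"band must satisfy 0 <= low <= high <= 1, got {band}")
    return [sp for sp in pairs if low <= sp.pair.alt_allele_freq <= high]


def is_disparate(g: GenotypePair) -> bool:
    """True iff the pair is mismatched in the GVT direction.

    The recipient must present the MiHA (>= 1 positive allele) and the donor
    must lack it entirely (0 positive alleles), so donor T cells are
    non-tolerant.
    """
    g.validate()
    return g.recipient_alt_count >= 1 and g.donor_alt_count == 0


# ---------------------------------------------------------------------------
# Genotype table I/O

_GENO_STRING = {"AA": 0, "AB": 1, "BA": 1, "BB": 2}


def read_genotypes(
    path: str | Path,
    positive_allele: str = "B",
    sep: str = "\t",
) -> list[GenotypePair]:
    """Read a genotype table with numeric counts or AA/AB/BB genotype strings.

    Numeric form: columns ``snp_id, recipient_alt_count, donor_alt_count``.
    String form: columns ``snp_id, recipient_genotype, donor_genotype`` with
    genotypes in {AA, AB, BB}; ``positive_allele`` declares which letter is
    the MiHA-positive allele.
    """
    df = pd.read_csv(path, sep=sep)
    if {"recipient_alt_count", "donor_alt_count"}.issubset(df.columns):
        out = [
            GenotypePair(str(r.snp_id), int(r.recipient_alt_count), int(r.donor_alt_count))
            for r in df.itertuples(index=False)
        ]
    elif {"recipient_genotype", "donor_genotype"}.issubset(df.columns):
        if positive_allele not in ("A", "B"):
            raise ValueError(f"positive_allele must be 'A' or 'B', got {positive_allele!r}")

        def count(geno: str) -> int:
            geno = geno.strip().upper()
            if geno not in _GENO_STRING:
                raise ValueError(f"unknown genotype string {geno!r}")
            n_b = _GENO_STRING[geno]
            return n_b if positive_allele == "B" else 2 - n_b

        out = [
            GenotypePair(str(r.snp_id), count(str(r.recipient_genotype)),
                         count(str(r.donor_genotype)))
            for r in df.itertuples(index=False)
        ]
    else:
        raise ValueError(
            "genotype table needs either recipient_alt_count/donor_alt_count "
            "or recipient_genotype/donor_genotype columns"
        )
    for g in out:
        g.validate()
    return out
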