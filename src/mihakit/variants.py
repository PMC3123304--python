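"""Candidate epitope windows around nonsynonymous SNPs.

A nonsynonymous SNP substitutes a single amino acid in a protein; every
9- or 10-mer peptide window that covers the polymorphic residue is a
candidate allelic epitope pair (reference peptide vs. alternate peptide).
Coordinates are 1-based inclusive throughout, matching the convention of
"position 6 of the nonameric epitope".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical one-letter codes.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_AA)


class VariantValidationError(ValueError):
    """Raised when a variant record is inconsistent with its protein sequence."""


@dataclass(frozen=True)
class VariantRecord:
    """A protein carrying one nonsynonymous SNP.

    ``alt_allele_freq`` is the population frequency of the MiHA-positive
    allele (by convention the alternate allele; see :func:`swap_miha_allele`).
    """

    protein_id: str
    sequence: str
    position: int  # 1-based index of the polymorphic residue
    ref_aa: str
    alt_aa: str
    alt_allele_freq: float
    snp_id: str = ""

    def validate(self) -> None:
        if not (1 <= self.position <= len(self.sequence)):
            raise VariantValidationError(
                f"{self.protein_id}: position {self.position} outside protein "
                f"of length {len(self.sequence)}"
            )
        found = self.sequence[self.position - 1]
        if found != self.ref_aa:
            raise VariantValidationError(
                f"{self.protein_id}: reference residue mismatch at position "
                f"{self.position}: sequence has {found!r}, record says {self.ref_aa!r}"
            )
        if self.ref_aa == self.alt_aa:
            raise VariantValidationError(
                f"{self.protein_id}: synonymous record (ref == alt == {self.ref_aa!r}) "
                f"at position {self.position}"
            )
        if not (0.0 <= self.alt_allele_freq <= 1.0):
            raise VariantValidationError(
                f"{self.protein_id}: allele frequency {self.alt_allele_freq} "
                "outside [0, 1]"
            )


@dataclass(frozen=True)
class AllelicPeptidePair:
    """Reference/alternate peptide windows covering a polymorphic residue."""

    protein_id: str
    start: int  # 1-based start of the window in the protein
    length: int
    variant_offset: int  # 1-based position of the polymorphism within the peptide
    ref_peptide: str
    alt_peptide: str
    snp_id: str = ""
    alt_allele_freq: float = 0.0

    @property
    def pair_id(self) -> str:
        return f"{self.protein_id}:{self.start}-{self.start + self.length - 1}"


def swap_miha_allele(record: VariantRecord) -> VariantRecord:
    """Declare the *reference* allele MiHA-positive by swapping allele roles.

    The polymorphism is symmetric: which allele is "MiHA-positive" is a
    modeling choice. Swapping exchanges ref/alt amino acids (the stored
    sequence is re-anchored to the old alternate residue) and complements
    the allele frequency.
    """
    record.validate()
    seq = record.sequence
    new_seq = seq[: record.position - 1] + record.alt_aa + seq[record.position:]
    return replace(
        record,
        sequence=new_seq,
        ref_aa=record.alt_aa,
        alt_aa=record.ref_aa,
        alt_allele_freq=1.0 - record.alt_allele_freq,
    )


def enumerate_windows(
    record: VariantRecord, lengths: Iterable[int] = (9, 10)
) -> list[AllelicPeptidePair]:
    """Enumerate every peptide window covering the variant position.

    For each requested length L, every substring of length L that lies
    fully within the protein and contains the polymorphic residue is
    emitted as a ref/alt pair. Windows containing non-standard residues
    (X, U, B, Z, ...) are skipped with a warning, since downstream binding
    coefficients are defined over the 20-letter alphabet only.

    Output is ordered by (length, start), deterministic for identical input.
    """
    lengths = sorted(set(int(x) for x in lengths))
    if not lengths or any(x < 1 for x in lengths):
        raise ValueError(f"window lengths must be positive, got {lengths}")
    record.validate()

    seq = record.sequence
    n = len(seq)
    pos = record.position
    pairs: list[AllelicPeptidePair] = []
    for length in lengths:
        # starts s (1-based) with s <= pos <= s+length-1 and window in-bounds
        lo = max(1, pos - length + 1)
        hi = min(pos, n - length + 1)
        for start in range(lo, hi + 1):
            ref_pep = seq[start - 1 : start - 1 + length]
            if not _STANDARD_SET.issuperset(ref_pep):
                logger.warning(
                    "skipping window %s:%d-%d containing non-standard residue(s): %s",
                    record.protein_id, start, start + length - 1, ref_pep,
                )
                continue
            offset = pos - start + 1
            alt_pep = ref_pep[: offset - 1] + record.alt_aa + ref_pep[offset:]
            pairs.append(
                AllelicPeptidePair(
                    protein_id=record.protein_id,
                    start=start,
                    length=length,
                    variant_offset=offset,
                    ref_peptide=ref_pep,
                    alt_peptide=alt_pep,
                    snp_id=record.snp_id,
                    alt_allele_freq=record.alt_allele_freq,
                )
            )
    return pairs


# ---------------------------------------------------------------------------
# I/O

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences; the id is the first whitespace token of the header."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


VARIANT_COLUMNS = [
    "protein_id", "position", "ref_aa", "alt_aa", "alt_allele_freq", "snp_id",
]


def read_variants(
    path: str | Path,
    sequences: dict[str, str],
    miha_positive: str = "alt",
    sep: str = "\t",
) -> list[VariantRecord]:
    """Read a delimited variant table and join it to protein sequences.

    ``miha_positive`` may be ``"alt"`` (default: the table's alternate allele
    is the MiHA-positive one) or ``"ref"`` (roles swapped on load).
    """
    if miha_positive not in ("alt", "ref"):
        raise ValueError(f"miha_positive must be 'alt' or 'ref', got {miha_positive!r}")
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        pid = str(row.protein_id)
        if pid not in sequences:
            raise KeyError(f"protein {pid!r} not present in FASTA input")
        rec = VariantRecord(
            protein_id=pid,
            sequence=sequences[pid],
            position=int(row.position),
            ref_aa=str(row.ref_aa),
            alt_aa=str(row.alt_aa),
            alt_allele_freq=float(row.alt_allele_freq),
            snp_id=str(row.snp_id),
        )
        rec.validate()
        if miha_positive == "ref":
            rec = swap_miha_allele(rec)
        records.append(rec)
    return records


def pairs_to_frame(pairs: Iterable[AllelicPeptidePair]) -> pd.DataFrame:
    """Tabulate peptide pairs for delimited output."""
    return pd.DataFrame(
        [
            {
                "protein_id": p.protein_id,
                "start": p.start,
                "length": p.length,
                "variant_offset": p.variant_offset,
                "ref_peptide": p.ref_peptide,
                "alt_peptide": p.alt_peptide,
                "snp_id": p.snp_id,
                "alt_allele_freq": p.alt_allele_freq,
            }
            for p in pairs
        ],
        columns=[
            "protein_id", "start", "length", "variant_offset",
            "ref_peptide", "alt_peptide", "snp_id", "alt_allele_freq",
        ],
    )


def frame_to_pairs(df: pd.DataFrame) -> list[AllelicPeptidePair]:
    return [
        AllelicPeptidePair(
            protein_id=str(r.protein_id),
            start=int(r.start),
            length=int(r.length),
            variant_offset=int(r.variant_offset),
            ref_peptide=str(r.ref_peptide),
            alt_peptide=str(r.alt_peptide),
            snp_id=str(r.snp_id),
            alt_allele_freq=float(r.alt_allele_freq),
        )
        for r in df.itertuples(index=False)
    ]
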