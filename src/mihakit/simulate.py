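"""Seeded synthetic-data generators with ground truth for every pipeline stage.

Real inputs to the pipeline come from sequence repositories (proteins and
nonsynonymous SNPs), an exchange-ELISA plate reader (ODs), a genotyping
assay and a cytometer (event tables). None of those can be queried in an
offline test, so each generator here emulates one input class and records
the ground truth needed to score the downstream stage:

* :func:`simulate_variants` — random proteins, one embedded substitution
  each, allele frequencies drawn uniformly; truth marks which variants fall
  in the default applicability band.
* :func:`simulate_od` — class-structured ODs (low/intermediate/high drawn
  from disjoint uniform ranges), so classification is exactly recoverable.
* :func:`simulate_events` — cytometry event tables with spiked-in
  dual-positive populations plus single- and triple-positive noise; the
  intensity model is two log-normal components (negative/positive) per
  channel, separated widely enough that fixed-threshold gating is exact.
* :func:`simulate_genotypes` — donor/recipient genotypes drawn
  independently from Hardy-Weinberg proportions.

Identical seed, identical output — byte-for-byte when written to disk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .applicability import DEFAULT_BAND
from .binding import CoefficientTable
from .elisa import AffinityClass
from .flow import GatingConfig
from .panel import PanelAssignment
from .variants import STANDARD_AA, VariantRecord

#: Fixture seed used throughout the docs and shipped examples.
DEFAULT_SEED = 20110624

# Stream ids keep the four generators' randomness independent under one seed.
_STREAM = {"variants": 1, "od": 2, "events": 3, "genotypes": 4, "coefficients": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAM[stream]])


# ---------------------------------------------------------------------------
# Configs


@dataclass(frozen=True)
class VariantSimConfig:
    n_proteins: int = 50
    protein_length_range: tuple[int, int] = (30, 80)
    freq_range: tuple[float, float] = (0.01, 0.6)


@dataclass(frozen=True)
class ODSimConfig:
    """Class weights default to the 32/33/42 split of a 107-peptide screen."""

    n_peptides: int = 107
    class_weights: tuple[float, float, float] = (32 / 107, 33 / 107, 42 / 107)
    low_range: tuple[float, float] = (0.0, 0.39)
    intermediate_range: tuple[float, float] = (0.4, 1.24)
    high_range: tuple[float, float] = (1.25, 2.5)
    #: When set, realize exactly these (low, intermediate, high) counts
    #: instead of multinomial draws; class order is shuffled across peptides.
    exact_counts: tuple[int, int, int] | None = None


@dataclass(frozen=True)
class FlowSimConfig:
    """Event-table model.

    Fractions are conditional: ``live_fraction`` of all events, then
    ``dump_neg_fraction`` of live events, then ``cd8_fraction`` of live
    dump-negative events. Spike frequencies are per-specificity fractions
    *among gated CD8+ events*; single/triple noise rates likewise.
    Intensities are two log-normal components per channel, parameterized on
    the log scale.
    """

    n_events: int = 100_000
    live_fraction: float = 0.95
    dump_neg_fraction: float = 0.90
    cd8_fraction: float = 0.70
    spike_frequencies: dict = field(default_factory=dict)  # peptide_id -> fraction
    single_noise_rate: float = 0.01
    triple_noise_rate: float = 0.002
    neg_log_mean: float = math.log(50.0)
    neg_log_sd: float = 0.4
    pos_log_mean: float = math.log(10_000.0)
    pos_log_sd: float = 0.5

    def default_gating(self, channels: tuple[str, ...]) -> GatingConfig:
        """A linear threshold at 1000 separates the two intensity components
        by > 7 negative-component log-SDs."""
        thr = {ch: 1000.0 for ch in channels}
        thr.update({
            "viability_intensity": 1000.0,
            "dump_intensity": 1000.0,
            "cd8_intensity": 1000.0,
        })
        return GatingConfig(thresholds=thr, transform="linear")


@dataclass(frozen=True)
class GenotypeSimConfig:
    n_pairs_per_snp: int = 1000
    allele_freqs: dict = field(default_factory=dict)  # snp_id -> p


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = DEFAULT_SEED
    variants: VariantSimConfig = field(default_factory=VariantSimConfig)
    od: ODSimConfig = field(default_factory=ODSimConfig)
    flow: FlowSimConfig = field(default_factory=FlowSimConfig)
    genotype: GenotypeSimConfig = field(default_factory=GenotypeSimConfig)


# ---------------------------------------------------------------------------
# Variants


@dataclass(frozen=True)
class VariantSimResult:
    records: tuple[VariantRecord, ...]
    sequences: dict  # protein_id -> sequence
    table: pd.DataFrame  # the variant table as written to disk
    truth: pd.DataFrame  # protein_id, snp_id, alt_allele_freq, truth_in_band


def simulate_variants(cfg: SimulationConfig) -> VariantSimResult:
    c = cfg.variants
    rng = _rng(cfg.seed, "variants")
    lo, hi = c.protein_length_range
    aa = np.array(list(STANDARD_AA))
    records: list[VariantRecord] = []
    for i in range(c.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(aa, size=length))
        pos = int(rng.integers(1, length + 1))
        ref = seq[pos - 1]
        alt = str(rng.choice([a for a in STANDARD_AA if a != ref]))
        freq = float(rng.uniform(*c.freq_range))
        records.append(
            VariantRecord(
                protein_id=f"PROT{i:04d}",
                sequence=seq,
                position=pos,
                ref_aa=ref,
                alt_aa=alt,
                alt_allele_freq=freq,
                snp_id=f"rs{int(rng.integers(10_000, 99_999_999))}",
            )
        )
    table = pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in records],
            "position": [r.position for r in records],
            "ref_aa": [r.ref_aa for r in records],
            "alt_aa": [r.alt_aa for r in records],
            "alt_allele_freq": [r.alt_allele_freq for r in records],
            "snp_id": [r.snp_id for r in records],
        }
    )
    truth = pd.DataFrame(
        {
            "protein_id": table["protein_id"],
            "snp_id": table["snp_id"],
            "alt_allele_freq": table["alt_allele_freq"],
            "truth_in_band": [
                DEFAULT_BAND[0] <= f <= DEFAULT_BAND[1]
                for f in table["alt_allele_freq"]
            ],
        }
    )
    return VariantSimResult(
        records=tuple(records),
        sequences={r.protein_id: r.sequence for r in records},
        table=table,
        truth=truth,
    )


def fasta_text(sequences: dict, width: int = 60) -> str:
    chunks = []
    for pid, seq in sequences.items():
        chunks.append(f">{pid}")
        chunks.extend(seq[i : i + width] for i in range(0, len(seq), width))
    return "\n".join(chunks) + "\n"


# ---------------------------------------------------------------------------
# ELISA ODs

_CLASS_ORDER = (AffinityClass.LOW, AffinityClass.INTERMEDIATE, AffinityClass.HIGH)


def simulate_od(cfg: SimulationConfig, peptides: list[str] | None = None) -> pd.DataFrame:
    """OD table with columns peptide, od, truth_class.

    ODs are drawn from the per-class uniform ranges, so re-classifying the
    drawn value always recovers the truth class.
    """
    c = cfg.od
    rng = _rng(cfg.seed, "od")
    if peptides is None:
        peptides = [f"PEP{i:04d}" for i in range(c.n_peptides)]
    n = len(peptides)
    if c.exact_counts is not None:
        if sum(c.exact_counts) != n:
            raise ValueError(
                f"exact_counts {c.exact_counts} must sum to the number of "
                f"peptides ({n})"
            )
        classes = np.repeat(np.arange(3), c.exact_counts)
        rng.shuffle(classes)
    else:
        classes = rng.choice(3, size=n, p=np.asarray(c.class_weights) / sum(c.class_weights))
    ranges = (c.low_range, c.intermediate_range, c.high_range)
    od = np.array([rng.uniform(*ranges[k]) for k in classes])
    return pd.DataFrame(
        {
            "peptide": peptides,
            "od": od,
            "truth_class": [_CLASS_ORDER[k].value for k in classes],
        }
    )


# ---------------------------------------------------------------------------
# Flow events


@dataclass(frozen=True)
class EventSimResult:
    events: pd.DataFrame
    truth: pd.DataFrame  # per-event: statuses and truth_label
    gating: GatingConfig


def simulate_events(cfg: SimulationConfig, panel: PanelAssignment) -> EventSimResult:
    """Cytometry event table for ``panel`` with spiked-in specificities.

    Among gated (live, dump-negative, CD8+) events each specificity label is
    drawn at its spike frequency; leftover probability mass goes to
    single-positive noise, triple-positive noise and true negatives. A
    labeled event receives positive intensity in exactly its code's two
    channels; noise events in 1 or 3 uniformly chosen channels.
    """
    c = cfg.flow
    rng = _rng(cfg.seed, "events")
    channels = list(panel.fluorochromes.channels)
    spikes = dict(c.spike_frequencies)
    unknown = set(spikes) - set(panel.entries)
    if unknown:
        raise ValueError(f"spike frequencies for peptides not in panel: {sorted(unknown)}")
    mass = sum(spikes.values()) + c.single_noise_rate + c.triple_noise_rate
    if mass > 1.0:
        raise ValueError(f"spike + noise probability mass {mass} exceeds 1")

    n = c.n_events
    live = rng.random(n) < c.live_fraction
    dump_neg = live & (rng.random(n) < c.dump_neg_fraction)
    cd8 = dump_neg & (rng.random(n) < c.cd8_fraction)

    # Per-gated-event truth label.
    label_names = list(spikes) + ["noise_single", "noise_triple", "negative"]
    probs = list(spikes.values()) + [c.single_noise_rate, c.triple_noise_rate,
                                     1.0 - mass]
    labels = np.full(n, "ungated", dtype=object)
    gated_idx = np.flatnonzero(cd8)
    labels[gated_idx] = rng.choice(label_names, size=gated_idx.size, p=probs)

    def draw(shape, positive: bool) -> np.ndarray:
        if positive:
            return rng.lognormal(c.pos_log_mean, c.pos_log_sd, shape)
        return rng.lognormal(c.neg_log_mean, c.neg_log_sd, shape)

    # Start fully negative, then overwrite positives channel by channel.
    intens = {ch: draw(n, False) for ch in channels}
    viability = np.where(live, draw(n, False), draw(n, True))
    dump = np.where(~live | dump_neg, draw(n, False), draw(n, True))
    cd8_int = np.where(cd8, draw(n, True), draw(n, False))

    for i in gated_idx:
        lab = labels[i]
        if lab == "negative":
            continue
        if lab == "noise_single":
            pos_channels = rng.choice(channels, size=1, replace=False)
        elif lab == "noise_triple":
            pos_channels = rng.choice(channels, size=3, replace=False)
        else:
            pos_channels = sorted(panel.entries[lab])
        for ch in pos_channels:
            intens[ch][i] = draw((), True)

    events = pd.DataFrame(
        {
            **{ch: intens[ch] for ch in channels},
            "cd8_intensity": cd8_int,
            "dump_intensity": dump,
            "viability_intensity": viability,
        }
    )
    truth = pd.DataFrame(
        {
            "is_live": live,
            "is_dump_neg": dump_neg,
            "is_cd8": cd8,
            "truth_label": labels,
        }
    )
    return EventSimResult(events=events, truth=truth,
                          gating=c.default_gating(tuple(channels)))


# ---------------------------------------------------------------------------
# Genotypes


def simulate_genotypes(
    cfg: SimulationConfig,
    snps: dict | None = None,
) -> pd.DataFrame:
    """Donor/recipient genotype pairs drawn independently from HWE.

    ``snps`` maps snp_id to MiHA-positive allele frequency (defaults to
    ``cfg.genotype.allele_freqs``). Output columns: snp_id,
    recipient_alt_count, donor_alt_count, truth_disparate.
    """
    c = cfg.genotype
    rng = _rng(cfg.seed, "genotypes")
    freqs = dict(snps if snps is not None else c.allele_freqs)
    ids, recips, donors = [], [], []
    for snp_id, p in freqs.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{snp_id}: allele frequency {p} outside [0, 1]")
        ids.extend([snp_id] * c.n_pairs_per_snp)
        recips.append(rng.binomial(2, p, size=c.n_pairs_per_snp))
        donors.append(rng.binomial(2, p, size=c.n_pairs_per_snp))
    recip = np.concatenate(recips) if recips else np.array([], dtype=int)
    donor = np.concatenate(donors) if donors else np.array([], dtype=int)
    return pd.DataFrame(
        {
            "snp_id": ids,
            "recipient_alt_count": recip,
            "donor_alt_count": donor,
            "truth_disparate": (recip >= 1) & (donor == 0),
        }
    )


# ---------------------------------------------------------------------------
# Coefficient tables


def random_coefficient_table(
    length: int,
    seed: int = DEFAULT_SEED,
    allele: str = "HLA-A2",
    constant: float = 5.0,
) -> CoefficientTable:
    """A seeded synthetic coefficient table for testing the scoring path.

    Coefficients are log-normal around 1, mimicking the shape of published
    matrices (most positions near-neutral, anchors far from 1). This is a
    synthetic stand-in, not a published matrix.
    """
    rng = np.random.default_rng([seed, _STREAM["coefficients"], length])
    coeff = rng.lognormal(mean=0.0, sigma=1.0, size=(length, 20))
    return CoefficientTable(allele=allele, length=length, coefficients=coeff,
                            constant=constant)
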