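"""Flow-cytometry gating and combinatorial dual-positive decoding.

Event tables are plain pandas DataFrames: one row per event, one column of
raw intensity per multimer channel plus three gating channels
(``cd8_intensity``, ``dump_intensity``, ``viability_intensity``). The dump
channel pools lineage markers (CD4/CD14/CD16/CD19 on FITC); the viability
channel is a dead-cell dye.

Analysis follows the standard combinatorial-multimer gating strategy:
live (viability-negative), dump-negative, CD8-positive lymphocytes are
selected, then an event is assigned to a specificity only if it is
positive in *exactly* the two channels of that specificity's color code —
events positive in one, three or more channels are counted and excluded,
which is what corrects the readout for single/triple/quadruple-positive
artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .panel import ColorCode, PanelAssignment

logger = logging.getLogger(__name__)

GATING_COLUMNS = ("viability_intensity", "dump_intensity", "cd8_intensity")

TRANSFORMS = ("linear", "log", "asinh")


@dataclass(frozen=True)
class GatingConfig:
    """Per-channel positivity thresholds on transformed intensities.

    ``transform`` is applied to raw intensities before comparison:
    ``linear`` (identity), ``log`` (log10 of intensity clipped at 1), or
    ``asinh`` (inverse hyperbolic sine with ``cofactor``, the conventional
    cytometry variance-stabilizer). ``threshold_mode`` records whether the
    thresholds were fixed by the user or derived as a quantile of a
    negative-control table (see :meth:`from_negative_control`).
    """

    thresholds: dict  # channel -> threshold on the transformed scale
    transform: str = "linear"
    cofactor: float = 150.0
    threshold_mode: str = "fixed"

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ValueError(f"transform must be one of {TRANSFORMS}, "
                             f"got {self.transform!r}")
        if self.transform == "asinh" and not self.cofactor > 0:
            raise ValueError(f"asinh cofactor must be positive, got {self.cofactor}")
        for ch, thr in self.thresholds.items():
            if not np.isfinite(thr):
                raise ValueError(f"threshold for {ch!r} is not finite")

    def apply_transform(self, values: np.ndarray | pd.Series) -> np.ndarray:
        x = np.asarray(values, dtype=float)
        if self.transform == "linear":
            return x
        if self.transform == "log":
            return np.log10(np.maximum(x, 1.0))
        return np.arcsinh(x / self.cofactor)

    def threshold_for(self, channel: str) -> float:
        if channel not in self.thresholds:
            raise KeyError(f"no positivity threshold configured for channel {channel!r}")
        return float(self.thresholds[channel])

    def is_positive(self, events: pd.DataFrame, channel: str) -> np.ndarray:
        if channel not in events.columns:
            raise KeyError(f"event table has no column {channel!r}")
        return self.apply_transform(events[channel]) > self.threshold_for(channel)

    @classmethod
    def from_negative_control(
        cls,
        negatives: pd.DataFrame,
        channels: list[str],
        quantile: float = 0.999,
        transform: str = "linear",
        cofactor: float = 150.0,
    ) -> "GatingConfig":
        """Derive thresholds as a quantile of an unstained-control table."""
        probe = cls(thresholds={}, transform=transform, cofactor=cofactor)
        thresholds = {
            ch: float(np.quantile(probe.apply_transform(negatives[ch]), quantile))
            for ch in channels
        }
        return cls(thresholds=thresholds, transform=transform, cofactor=cofactor,
                   threshold_mode="quantile-of-negatives")


@dataclass(frozen=True)
class DecodedResult:
    """Per-specificity counts and frequencies among gated CD8+ events."""

    n_total_events: int
    n_cd8_gated: int
    assigned_counts: dict  # peptide_id -> int
    n_unassigned_single: int
    n_unassigned_multi: int  # positive in >= 3 channels, or an unmatched pair
    n_negative: int
    assignments: pd.Series = field(repr=False, default=None)  # per-event label

    @property
    def frequencies(self) -> dict:
        """Percentage of gated CD8+ events per specificity."""
        if self.n_cd8_gated == 0:
            return {pid: 0.0 for pid in self.assigned_counts}
        return {
            pid: 100.0 * n / self.n_cd8_gated
            for pid, n in self.assigned_counts.items()
        }

    def to_frame(self) -> pd.DataFrame:
        freqs = self.frequencies
        return pd.DataFrame(
            {
                "peptide_id": list(self.assigned_counts),
                "n_events": list(self.assigned_counts.values()),
                "frequency_pct": [freqs[p] for p in self.assigned_counts],
                "frequency_display": [format_frequency(freqs[p])
                                      for p in self.assigned_counts],
            }
        )


def format_frequency(pct: float) -> str:
    """Render a percentage to 2 decimals; sub-detection values as '<0.01%'."""
    if 0 < pct < 0.01:
        return "<0.01%"
    return f"{pct:.2f}%"


def gate_cd8(events: pd.DataFrame, cfg: GatingConfig) -> pd.DataFrame:
    """Select live, dump-negative, CD8-positive events.

    Gates are applied in that order (viability, then dump, then CD8); the
    result is their conjunction, but per-gate event counts are logged in
    sequence as a cytometrist would review them. The returned subset
    carries ``attrs['gate_counts']`` and ``attrs['n_total_events']``.
    """
    for col in GATING_COLUMNS:
        if col not in events.columns:
            raise KeyError(f"event table is missing gating column {col!r}")
    live = ~cfg.is_positive(events, "viability_intensity")
    dump_neg = live & ~cfg.is_positive(events, "dump_intensity")
    cd8 = dump_neg & cfg.is_positive(events, "cd8_intensity")
    counts = {
        "total": int(len(events)),
        "live": int(live.sum()),
        "live_dump_neg": int(dump_neg.sum()),
        "live_dump_neg_cd8_pos": int(cd8.sum()),
    }
    logger.info("gating: %s", counts)
    gated = events.loc[cd8]
    gated.attrs["gate_counts"] = counts
    gated.attrs["n_total_events"] = counts["total"]
    return gated


def decode_events(
    gated: pd.DataFrame,
    panel: PanelAssignment,
    cfg: GatingConfig,
) -> DecodedResult:
    """Decode gated events into per-specificity frequencies.

    An event is assigned to the specificity whose two-channel code equals
    its positive-channel set exactly. Events positive in one channel are
    counted ``unassigned_single``; in three or more channels, or in a
    two-channel combination no panel code claims, ``unassigned_multi``.
    Exclusion of those events is the correction for single/triple/quadruple
    multimer-positive artifacts.
    """
    channels = list(panel.fluorochromes.channels)
    missing = [c for c in channels if c not in gated.columns]
    if missing:
        raise KeyError(f"event table is missing multimer channel(s): {missing}")
    n_gated = len(gated)
    pos = np.column_stack(
        [cfg.is_positive(gated, ch) for ch in channels]
    ) if n_gated else np.zeros((0, len(channels)), dtype=bool)
    n_pos = pos.sum(axis=1)

    code_to_pid = panel.code_to_peptide()
    assigned_counts = {pid: 0 for pid in panel.entries}
    labels = np.full(n_gated, "negative", dtype=object)
    labels[n_pos == 1] = "unassigned_single"
    labels[n_pos >= 3] = "unassigned_multi"

    n_unmatched_pair = 0
    for i in np.flatnonzero(n_pos == 2):
        code = frozenset(ch for ch, flag in zip(channels, pos[i]) if flag)
        pid = code_to_pid.get(code)
        if pid is None:
            n_unmatched_pair += 1
            labels[i] = "unassigned_multi"
        else:
            assigned_counts[pid] += 1
            labels[i] = pid
    if n_unmatched_pair:
        logger.info("%d dual-positive events matched no panel code", n_unmatched_pair)

    return DecodedResult(
        n_total_events=int(gated.attrs.get("n_total_events", n_gated)),
        n_cd8_gated=n_gated,
        assigned_counts=assigned_counts,
        n_unassigned_single=int((n_pos == 1).sum()),
        n_unassigned_multi=int((n_pos >= 3).sum()) + n_unmatched_pair,
        n_negative=int((n_pos == 0).sum()),
        assignments=pd.Series(labels, index=gated.index, name="assignment"),
    )


def dual_color_frequency(gated: pd.DataFrame, code: ColorCode, cfg: GatingConfig) -> float:
    """Conventional dual-color readout: % of gated events positive in both
    channels of ``code``, ignoring all other multimer channels.

    Always >= the combinatorially decoded frequency for the same code, which
    additionally excludes events positive elsewhere.
    """
    if len(code) != 2:
        raise ValueError(f"code must name exactly 2 channels, got {sorted(code)}")
    for ch in code:
        if ch not in gated.columns:
            raise KeyError(f"event table has no column {ch!r}")
    if len(gated) == 0:
        return 0.0
    both = np.logical_and.reduce([cfg.is_positive(gated, ch) for ch in sorted(code)])
    return 100.0 * float(both.sum()) / len(gated)


# ---------------------------------------------------------------------------
# I/O

def read_events(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    if not np.isfinite(df.select_dtypes("number").to_numpy()).all():
        raise ValueError(f"{path}: event intensities must all be finite")
    return df


def write_events(events: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    events.to_csv(path, sep=sep, index=False)


def read_gating_config(path: str | Path) -> GatingConfig:
    """Load a YAML gating config: keys transform, cofactor, thresholds."""
    raw = yaml.safe_load(Path(path).read_text())
    return GatingConfig(
        thresholds={str(k): float(v) for k, v in raw["thresholds"].items()},
        transform=raw.get("transform", "linear"),
        cofactor=float(raw.get("cofactor", 150.0)),
        threshold_mode=raw.get("threshold_mode", "fixed"),
    )
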