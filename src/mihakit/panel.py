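"""Combinatorial dual-fluorochrome panel design and pool packing.

Each peptide specificity in a combinatorial multimer panel is encoded by an
unordered pair of fluorochromes, so k channels resolve up to C(k, 2)
specificities — 15 with six fluorochromes, 10 with five. A screening run
packs multimers into pools bounded by that capacity, seeding each leading
pool with one positive-control multimer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations, islice
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

#: Default six-channel multimer detector set, in enumeration order.
DEFAULT_CHANNELS = ("PE", "APC", "Qdot605", "Qdot655", "Qdot705", "Qdot800")


@dataclass(frozen=True)
class FluorochromeSet:
    """An ordered set of fluorochrome channel names; order fixes code enumeration."""

    channels: tuple[str, ...] = DEFAULT_CHANNELS

    def __post_init__(self) -> None:
        channels = tuple(self.channels)
        if len(set(channels)) != len(channels):
            raise ValueError(f"duplicate channel names in {channels}")
        object.__setattr__(self, "channels", channels)

    def __len__(self) -> int:
        return len(self.channels)

    def __contains__(self, name: str) -> bool:
        return name in self.channels


#: An unordered two-channel code.
ColorCode = frozenset


def make_code(a: str, b: str) -> ColorCode:
    if a == b:
        raise ValueError(f"a color code needs two distinct channels, got {a!r} twice")
    return frozenset((a, b))


@dataclass(frozen=True)
class PanelAssignment:
    """A peptide-id → unordered fluorochrome-pair code map."""

    entries: dict  # peptide_id -> ColorCode
    fluorochromes: FluorochromeSet = field(default_factory=FluorochromeSet)

    def code_to_peptide(self) -> dict:
        return {code: pid for pid, code in self.entries.items()}


@dataclass(frozen=True)
class PoolLayout:
    pools: tuple[tuple[str, ...], ...]
    capacity: int
    control_ids: tuple[str, ...] = ()

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(len(p) for p in self.pools)

    def pool_names(self) -> tuple[str, ...]:
        """Pools are lettered A, B, C, ... in order."""
        return tuple(chr(ord("A") + i) for i in range(len(self.pools)))


def capacity(k: int) -> int:
    """Number of specificities resolvable with k fluorochromes: C(k, 2)."""
    if k < 2:
        raise ValueError(f"need at least 2 fluorochromes, got {k}")
    return k * (k - 1) // 2


def assign_codes(
    peptide_ids: Sequence[str],
    fluorochromes: FluorochromeSet | Sequence[str] = DEFAULT_CHANNELS,
) -> PanelAssignment:
    """Assign distinct dual-color codes to peptides, deterministically.

    Codes are enumerated lexicographically by (channel index, channel index)
    and handed to peptides in input order.
    """
    if not isinstance(fluorochromes, FluorochromeSet):
        fluorochromes = FluorochromeSet(tuple(fluorochromes))
    cap = capacity(len(fluorochromes))
    if len(peptide_ids) > cap:
        raise ValueError(
            f"{len(peptide_ids)} peptides exceed the capacity of "
            f"{len(fluorochromes)} fluorochromes ({cap} dual-color codes)"
        )
    if len(set(peptide_ids)) != len(peptide_ids):
        raise ValueError("peptide ids must be unique")
    codes = (frozenset(pair) for pair in combinations(fluorochromes.channels, 2))
    entries = dict(zip(peptide_ids, islice(codes, len(peptide_ids))))
    return PanelAssignment(entries=entries, fluorochromes=fluorochromes)


def validate_panel(assignment: PanelAssignment) -> list[str]:
    """Return human-readable violations; an empty list means the panel is valid."""
    violations: list[str] = []
    seen: dict = {}
    for pid, code in assignment.entries.items():
        if len(code) != 2:
            violations.append(f"{pid}: code must pair exactly 2 distinct channels, "
                              f"got {sorted(code)}")
            continue
        unknown = [c for c in code if c not in assignment.fluorochromes]
        for c in unknown:
            violations.append(f"{pid}: unknown channel {c!r}")
        if unknown:
            continue
        if code in seen:
            violations.append(
                f"duplicate code {tuple(sorted(code))} shared by {seen[code]} and {pid}"
            )
        else:
            seen[code] = pid
    return violations


def pack_pools(
    candidate_ids: Sequence[str],
    control_ids: Sequence[str] = (),
    pool_capacity: int = 15,
) -> PoolLayout:
    """Pack multimers into screening pools of bounded size.

    The total pool count is ceil((candidates + controls) / capacity).
    Controls are placed one per pool starting from the first pool;
    candidates then fill pools in input order up to capacity, the last pool
    holding the remainder. 75 candidates with 4 controls at capacity 15
    yield five pools of 15 and one pool of 4, controls in pools A-D.
    """
    n_items = len(candidate_ids) + len(control_ids)
    min_cap = 1 + (1 if control_ids else 0)
    if pool_capacity < min_cap:
        raise ValueError(f"pool capacity must be >= {min_cap}, got {pool_capacity}")
    if n_items == 0:
        return PoolLayout(pools=(), capacity=pool_capacity,
                          control_ids=tuple(control_ids))
    overlap = set(candidate_ids) & set(control_ids)
    if overlap:
        raise ValueError(f"ids appear as both candidate and control: {sorted(overlap)}")
    n_pools = math.ceil(n_items / pool_capacity)
    if len(control_ids) > n_pools:
        raise ValueError(
            f"{len(control_ids)} controls but only {n_pools} pools; "
            "one control per pool maximum"
        )
    pools: list[list[str]] = [[] for _ in range(n_pools)]
    for i, ctrl in enumerate(control_ids):
        pools[i].append(ctrl)
    it = iter(candidate_ids)
    for pool in pools:
        while len(pool) < pool_capacity:
            nxt = next(it, None)
            if nxt is None:
                break
            pool.append(nxt)
    leftover = list(it)
    if leftover:  # cannot happen: n_pools * capacity >= n_items
        raise AssertionError(f"unpacked candidates remain: {leftover}")
    return PoolLayout(
        pools=tuple(tuple(p) for p in pools),
        capacity=pool_capacity,
        control_ids=tuple(control_ids),
    )


# ---------------------------------------------------------------------------
# Panel file I/O: columns peptide_id, channel_1, channel_2, pool

def write_panel(
    assignment: PanelAssignment,
    path: str | Path,
    layout: PoolLayout | None = None,
) -> None:
    pool_of: dict[str, str] = {}
    if layout is not None:
        for name, pool in zip(layout.pool_names(), layout.pools):
            for pid in pool:
                pool_of[pid] = name
    order = {c: i for i, c in enumerate(assignment.fluorochromes.channels)}
    rows = []
    for pid, code in assignment.entries.items():
        a, b = sorted(code, key=lambda c: order.get(c, len(order)))
        rows.append({"peptide_id": pid, "channel_1": a, "channel_2": b,
                     "pool": pool_of.get(pid, "")})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_panel(
    path: str | Path,
    fluorochromes: FluorochromeSet | Sequence[str] | None = None,
) -> PanelAssignment:
    """Read a panel file; channels default to those present in the file,
    in first-appearance order."""
    df = pd.read_csv(path, sep="\t")
    needed = {"peptide_id", "channel_1", "channel_2"}
    if not needed.issubset(df.columns):
        raise ValueError(f"panel file must have columns {sorted(needed)}")
    if fluorochromes is None:
        seen: list[str] = []
        for _, row in df.iterrows():
            for c in (row["channel_1"], row["channel_2"]):
                if c not in seen:
                    seen.append(str(c))
        fluorochromes = FluorochromeSet(tuple(seen))
    elif not isinstance(fluorochromes, FluorochromeSet):
        fluorochromes = FluorochromeSet(tuple(fluorochromes))
    entries = {
        str(r.peptide_id): make_code(str(r.channel_1), str(r.channel_2))
        for r in df.itertuples(index=False)
    }
    if len(entries) != len(df):
        raise ValueError("duplicate peptide ids in panel file")
    return PanelAssignment(entries=entries, fluorochromes=fluorochromes)


def load_reference_panel() -> PanelAssignment:
    """The shipped ten-MiHA monitoring kit: 10 known MiHA encoded by all
    C(5,2) = 10 dual-color codes over PE, APC, Qdot605, Qdot655, Qdot705."""
    with resources.as_file(
        resources.files("mihakit.data").joinpath("miha_kit_panel.tsv")
    ) as p:
        return read_panel(p)
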