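"""Intergenerational CAG-repeat transmission summaries.

When an expanded CAG allele passes from parent to offspring its length
often changes; paternal transmission of expanded Htt alleles shows a
characteristic bias toward expansion.  Given parent and offspring
constitutive repeat lengths this module computes signed transmission
changes, the percentage of transmissions that expanded, and per-cross
mean +/- SD summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd


@dataclass(frozen=True)
class TransmissionEvent:
    parent_cag: int
    offspring_cag: int
    cross: str = ""
    delta: int = field(init=False)

    def __post_init__(self) -> None:
        if self.parent_cag <= 0 or self.offspring_cag <= 0:
            raise ValueError("repeat lengths must be positive")
        object.__setattr__(self, "delta", self.offspring_cag - self.parent_cag)


def transmission_delta(parent_cag: int, offspring_cag: int) -> int:
    """Signed repeat-length change on transmission (offspring minus parent)."""
    if parent_cag <= 0 or offspring_cag <= 0:
        raise ValueError("repeat lengths must be positive")
    return offspring_cag - parent_cag


def expansion_bias(
    events: Sequence[TransmissionEvent], count_zero_in_denominator: bool = True
) -> float:
    """Percentage of transmissions whose repeat expanded (delta > 0).

    Unchanged transmissions count as "not expanded" by default; set
    ``count_zero_in_denominator=False`` to restrict the denominator to
    transmissions that changed length at all.
    """
    if not events:
        raise ValueError("expansion_bias requires at least one event")
    if count_zero_in_denominator:
        pool = list(events)
    else:
        pool = [e for e in events if e.delta != 0]
        if not pool:
            raise ValueError("no length-changing transmissions in event list")
    n_expanded = sum(1 for e in pool if e.delta > 0)
    return 100.0 * n_expanded / len(pool)


def delta_summary(events: Sequence[TransmissionEvent]) -> pd.DataFrame:
    """Per-cross mean, sample SD (n-1) and count of transmission changes.

    SD is reported as NaN for a cross with a single event.
    """
    if not events:
        raise ValueError("delta_summary requires at least one event")
    df = pd.DataFrame(
        {"cross": [e.cross for e in events], "delta": [e.delta for e in events]}
    )
    out = df.groupby("cross", sort=True)["delta"].agg(
        mean="mean", sd="std", n="count"
    )
    return out.reset_index()


def read_transmissions(path: str | Path) -> list[TransmissionEvent]:
    """Read a tab-delimited table with columns parent_cag, offspring_cag, cross."""
    df = pd.read_csv(path, sep="\t")
    for col in ("parent_cag", "offspring_cag"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    crosses = df["cross"] if "cross" in df.columns else [""] * len(df)
    return [
        TransmissionEvent(int(p), int(o), str(c))
        for p, o, c in zip(df["parent_cag"], df["offspring_cag"], crosses)
    ]


def write_transmissions(
    events: Iterable[TransmissionEvent], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "parent_cag": e.parent_cag,
                "offspring_cag": e.offspring_cag,
                "delta": e.delta,
                "cross": e.cross,
            }
            for e in events
        ]
    ).to_csv(path, sep="\t", index=False)
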