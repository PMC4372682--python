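"""Body-weight traits and histology summary quantities per mouse.

Weight traits follow the standard growth-trait parameterisation for mouse
cohorts weighed weekly from weaning: weights read (or linearly
interpolated) at three anchor ages — initial (IW, ~25 d), medium (MW,
~98 d) and final (FW, ~169 d) — and per-day gain rates over the early
window (EWG), the late window (FWG) and the full window (WG), each a
simple endpoint difference divided by the number of days.

Histology summaries are arithmetic: the inclusion fraction is the number
of intranuclear huntingtin inclusions per hundred EM48-positive nuclei,
averaged over consecutive striatal sections; DARPP-32 intensity is the
per-section mean of an 8-bit staining intensity (0-255), and group effects
are expressed as percent reduction relative to a reference group mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import fmean
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

DAY_IW, DAY_MW, DAY_FW = 25, 98, 169


@dataclass(frozen=True)
class MouseRecord:
    """One animal's metadata, weight trajectory and histology readouts."""

    id: str
    sex: str  # "female" | "male"
    htt_genotype: str  # "Q111/+" | "+/+"
    chr10_background: str  # "B6J/B6J" | "B6J/AJ"
    constitutive_cag: Optional[int] = None
    weights: Mapping[float, float] = field(default_factory=dict)  # day -> grams
    inclusion_counts: Sequence[tuple[int, int]] = ()  # (n_inclusions, n_em48) per section
    darpp32_intensity: Sequence[float] = ()  # per-section mean intensity, 0-255

    def __post_init__(self) -> None:
        for day, w in self.weights.items():
            if day <= 0:
                raise ValueError(f"ages must be positive, got day {day}")
            if w < 0:
                raise ValueError(f"weights must be non-negative, got {w} g")
        for v in self.darpp32_intensity:
            if not 0 <= v <= 255:
                raise ValueError(f"intensity {v} outside [0, 255]")


@dataclass(frozen=True)
class WeightTraits:
    IW: float  # grams at the initial anchor age
    MW: float  # grams at the medium anchor age
    FW: float  # grams at the final anchor age
    EWG: float  # g/day over the early window
    FWG: float  # g/day over the late window
    WG: float  # g/day over the full window


def weight_traits(
    record: MouseRecord,
    day_iw: float = DAY_IW,
    day_mw: float = DAY_MW,
    day_fw: float = DAY_FW,
) -> WeightTraits:
    """Derive IW/MW/FW and the three per-day gain rates for one mouse.

    Anchor weights are read directly when a weighing fell on the anchor day
    and linearly interpolated between the flanking weekly weighings
    otherwise.  The weighing record must span every anchor; a missing
    endpoint raises a ValueError naming it.
    """
    if not record.weights:
        raise ValueError(f"mouse {record.id}: no weights recorded")
    days = np.array(sorted(record.weights), dtype=float)
    grams = np.array([record.weights[d] for d in days], dtype=float)
    anchors = {"IW": day_iw, "MW": day_mw, "FW": day_fw}
    values = {}
    for name, day in anchors.items():
        if day < days[0] or day > days[-1]:
            raise ValueError(
                f"mouse {record.id}: weighings cover days "
                f"[{days[0]:g}, {days[-1]:g}], cannot anchor {name} at day {day:g}"
            )
        values[name] = float(np.interp(day, days, grams))
    iw, mw, fw = values["IW"], values["MW"], values["FW"]
    return WeightTraits(
        IW=iw,
        MW=mw,
        FW=fw,
        EWG=(mw - iw) / (day_mw - day_iw),
        FWG=(fw - mw) / (day_fw - day_mw),
        WG=(fw - iw) / (day_fw - day_iw),
    )


def inclusion_fraction(n_inclusions: int, n_em48_cells: int) -> float:
    """Percent of EM48-positive nuclei bearing an inclusion, for one section."""
    if n_em48_cells <= 0:
        raise ValueError("n_em48_cells must be positive")
    if n_inclusions < 0:
        raise ValueError("n_inclusions must be non-negative")
    return 100.0 * n_inclusions / n_em48_cells


def mouse_inclusion_fraction(record: MouseRecord) -> float:
    """Per-mouse inclusion percentage: unweighted mean over sections."""
    if not record.inclusion_counts:
        raise ValueError(f"mouse {record.id}: no inclusion counts")
    return fmean(inclusion_fraction(i, n) for i, n in record.inclusion_counts)


def mouse_darpp32(record: MouseRecord) -> float:
    """Per-mouse DARPP-32 intensity: unweighted mean over sections."""
    if not record.darpp32_intensity:
        raise ValueError(f"mouse {record.id}: no intensity values")
    return fmean(record.darpp32_intensity)


def percent_reduction(mean_ref: float, mean_test: float) -> float:
    """Percent decrease of a test group mean relative to a reference mean."""
    if mean_ref <= 0:
        raise ValueError("reference mean must be positive")
    return 100.0 * (mean_ref - mean_test) / mean_ref


def trait_table(
    records: Sequence[MouseRecord],
    day_iw: float = DAY_IW,
    day_mw: float = DAY_MW,
    day_fw: float = DAY_FW,
) -> pd.DataFrame:
    """Per-mouse trait table: metadata, weight traits and histology means.

    Histology columns are NaN for mice without the corresponding readout.
    """
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "id": rec.id,
            "sex": rec.sex,
            "htt_genotype": rec.htt_genotype,
            "chr10_background": rec.chr10_background,
            "constitutive_cag": rec.constitutive_cag,
        }
        if rec.weights:
            traits = weight_traits(rec, day_iw, day_mw, day_fw)
            row.update(
                IW=traits.IW, MW=traits.MW, FW=traits.FW,
                EWG=traits.EWG, FWG=traits.FWG, WG=traits.WG,
            )
        row["inclusion_pct"] = (
            mouse_inclusion_fraction(rec) if rec.inclusion_counts else np.nan
        )
        row["darpp32"] = (
            mouse_darpp32(rec) if rec.darpp32_intensity else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)
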