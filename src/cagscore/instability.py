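"""Somatic instability scoring of CAG-repeat electropherogram traces.

A capillary-electrophoresis run of a PCR across an expanded CAG tract
produces a ladder of peaks, one per repeat length present in the template
pool.  In a mosaic tissue the ladder spreads away from the inherited
(constitutive) allele; the degree and direction of that spread is what the
metrics in this module quantify.

The central statistic is the *instability index*: peaks below a relative
height threshold (default 20 % of the tallest peak) are discarded, the
remaining heights are normalised to sum to one, and each peak's weight is
multiplied by its repeat-length change relative to the main allele.  The
signed sum is the instability index; restricting the sum to positive or
negative changes gives the expansion and contraction indices, which add up
to the instability index by construction.

Two pattern metrics describe the *shape* of the mosaicism rather than its
mass: the distance from the constitutive allele to the longest retained
repeat, and, for bimodal traces (typical of liver, where a discrete
population of highly expanded repeats coexists with the constitutive
population), the distance between the two modes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

logger = logging.getLogger(__name__)

DEFAULT_REL_THRESHOLD = 0.20
DEFAULT_MIN_SEPARATION = 5


@dataclass(frozen=True)
class RepeatTrace:
    """Peak ladder for one sample x tissue: repeat length -> peak height.

    Parameters
    ----------
    peaks
        Mapping from integer CAG repeat length to peak height (arbitrary
        fluorescence units, >= 0).  At least one peak must have positive
        height.
    constitutive_cag
        Inherited repeat length, normally the main allele of the same
        animal's tail trace.  Optional; scoring falls back to the trace's
        own main allele when absent.
    """

    peaks: Mapping[int, float]
    sample_id: str = ""
    tissue: str = "other"
    constitutive_cag: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError("trace must contain at least one peak")
        for cag, h in self.peaks.items():
            if int(cag) != cag or cag < 1:
                raise ValueError(f"CAG keys must be positive integers, got {cag!r}")
            if h < 0:
                raise ValueError(f"peak height must be >= 0, got {h!r} at CAG {cag}")
        if not any(h > 0 for h in self.peaks.values()):
            raise ValueError("all peak heights are zero")
        object.__setattr__(self, "peaks", dict(self.peaks))

    def total_height(self) -> float:
        return float(sum(self.peaks.values()))


@dataclass(frozen=True)
class InstabilityResult:
    """Indices and bookkeeping from scoring one trace."""

    sample_id: str
    tissue: str
    main_allele_cag: int
    instability_index: float
    expansion_index: float
    contraction_index: float
    retained_peaks: Mapping[int, float]  # CAG -> normalised weight, sums to 1
    threshold: float = DEFAULT_REL_THRESHOLD


@dataclass(frozen=True)
class PatternMetrics:
    """Mosaicism-shape metrics for one trace.

    ``distance_between_modes`` is ``None`` when fewer than two modes are
    detected (the unimodal tail/striatum pattern).
    """

    distance_to_longest: int
    distance_between_modes: Optional[int]
    modes: tuple[int, ...] = field(default_factory=tuple)


def call_main_allele(trace: RepeatTrace) -> int:
    """Return the repeat length of the highest peak (ties -> smaller CAG)."""
    best_cag = None
    best_h = -1.0
    for cag in sorted(trace.peaks):
        h = trace.peaks[cag]
        if h > best_h:
            best_h = h
            best_cag = cag
    if best_h <= 0:
        raise ValueError("cannot call main allele: all heights zero")
    return int(best_cag)


def filter_peaks(
    trace: RepeatTrace, rel_threshold: float = DEFAULT_REL_THRESHOLD
) -> RepeatTrace:
    """Drop peaks whose height is less than ``rel_threshold`` of the main allele.

    Peaks exactly at the threshold are retained ("less than" is excluded),
    and the main allele is always retained since it defines the cutoff.
    """
    if not 0 < rel_threshold < 1:
        raise ValueError(f"rel_threshold must be in (0, 1), got {rel_threshold}")
    main = call_main_allele(trace)
    cutoff = rel_threshold * trace.peaks[main]
    kept = {c: h for c, h in trace.peaks.items() if h >= cutoff or c == main}
    return replace(trace, peaks=kept)


def instability_index(
    trace: RepeatTrace, rel_threshold: float = DEFAULT_REL_THRESHOLD
) -> InstabilityResult:
    """Score a trace: threshold, normalise heights, sum weighted CAG changes.

    Over retained peaks *i* with heights *h_i* and repeat lengths *c_i*,
    and main allele *m*::

        w_i   = h_i / sum(h)
        index = sum_i w_i * (c_i - m)

    The expansion (contraction) index keeps only the terms with positive
    (negative) change, under the same shared normalisation, so that
    ``instability == expansion + contraction`` exactly.
    """
    kept = filter_peaks(trace, rel_threshold)
    main = call_main_allele(kept)
    total = kept.total_height()
    weights = {c: h / total for c, h in kept.peaks.items()}
    expansion = sum(w * (c - main) for c, w in weights.items() if c > main)
    contraction = sum(w * (c - main) for c, w in weights.items() if c < main)
    return InstabilityResult(
        sample_id=trace.sample_id,
        tissue=trace.tissue,
        main_allele_cag=main,
        instability_index=expansion + contraction,
        expansion_index=expansion,
        contraction_index=contraction,
        retained_peaks=weights,
        threshold=rel_threshold,
    )


def _resolve_constitutive(trace: RepeatTrace, constitutive: Optional[int]) -> int:
    if constitutive is not None:
        return int(constitutive)
    if trace.constitutive_cag is not None:
        return int(trace.constitutive_cag)
    main = call_main_allele(trace)
    logger.warning(
        "trace %s/%s has no constitutive CAG annotation; using its own main "
        "allele (%d)",
        trace.sample_id,
        trace.tissue,
        main,
    )
    return main


def distance_to_longest(
    trace: RepeatTrace,
    rel_threshold: float = DEFAULT_REL_THRESHOLD,
    constitutive: Optional[int] = None,
) -> int:
    """CAG distance from the constitutive allele to the longest retained repeat.

    Background correction is the same relative-height threshold used for the
    instability index.  Floored at zero when no retained peak exceeds the
    constitutive length.
    """
    constitutive = _resolve_constitutive(trace, constitutive)
    kept = filter_peaks(trace, rel_threshold)
    longest = max(kept.peaks)
    return max(0, int(longest) - constitutive)


def _find_modes(peaks: Mapping[int, float], min_separation: int) -> list[int]:
    """Local maxima of a sparse height profile, at least min_separation apart.

    A retained repeat length is a mode candidate when no retained peak
    strictly within ``min_separation`` repeats is taller (height ties break
    toward the smaller CAG).
    """
    cags = sorted(peaks)
    modes = []
    for c in cags:
        h = peaks[c]
        dominated = False
        for other in cags:
            if other == c or abs(other - c) >= min_separation:
                continue
            if peaks[other] > h or (peaks[other] == h and other < c):
                dominated = True
                break
        if not dominated:
            modes.append(c)
    return modes


def distance_between_modes(
    trace: RepeatTrace,
    rel_threshold: float = DEFAULT_REL_THRESHOLD,
    min_separation: int = DEFAULT_MIN_SEPARATION,
    constitutive: Optional[int] = None,
) -> PatternMetrics:
    """Detect modes of the retained profile and measure their separation.

    Modes are local maxima of the post-threshold ladder separated by at
    least ``min_separation`` repeats; the two tallest (ties toward smaller
    CAG) are taken as the constitutive and somatically expanded populations.
    ``distance_between_modes`` is absent for unimodal traces.
    """
    kept = filter_peaks(trace, rel_threshold)
    candidates = _find_modes(kept.peaks, min_separation)
    # two tallest candidates; ties broken toward the smaller repeat length
    top = sorted(candidates, key=lambda c: (-kept.peaks[c], c))[:2]
    dist = abs(top[1] - top[0]) if len(top) == 2 else None
    return PatternMetrics(
        distance_to_longest=distance_to_longest(trace, rel_threshold, constitutive),
        distance_between_modes=dist,
        modes=tuple(sorted(top)),
    )
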