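"""Synthetic electropherograms, cohorts and transmissions.

No public raw traces or per-animal tables exist for this study design, so
every pipeline stage is exercised against simulated data whose statistical
structure matches what the analysis assumes:

* **Traces** — tail DNA is stable: a single constitutive mode flanked only
  by PCR-stutter peaks (geometric decay on the contraction side, the
  dominant artifact direction for CAG amplification).  Striatum shows the
  constitutive mode plus a broad one-sided expanded tail (discretised
  gamma over positive repeat changes).  Liver is bimodal: constitutive
  mode plus a distinct somatically expanded mode at a fixed repeat offset.
  Peak heights receive multiplicative lognormal noise of a chosen CV.
* **Cohorts** — per-mouse weekly weight trajectories, linear in age with
  background- and sex-specific intercept and slope; histology readouts
  (inclusion percentages, DARPP-32 intensities) drawn from group-specific
  normals.  Default group parameters are the published cohort means/SDs.
* **Transmissions** — paternal transmissions expand with probability
  ``p_expand``; change magnitudes follow a discretised half-normal with a
  minimum of one repeat.

Every generator takes an explicit seed; there is no hidden global RNG.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .instability import RepeatTrace
from .phenotypes import MouseRecord
from .transmission import TransmissionEvent

MAIN_PEAK_HEIGHT = 10_000.0  # arbitrary fluorescence units for the tallest peak
_STUTTER_FLOOR = 1e-4  # stop extending a stutter ladder below this relative mass
CAG_RANGE = (133, 149)  # constitutive repeat lengths seen in the F1 progeny


@dataclass(frozen=True)
class TissueProfile:
    """Generating parameters for one tissue's repeat-length distribution.

    ``expansion_mean``/``expansion_sd`` parameterise the somatic expansion
    mass in repeat units; for liver the expanded mass sits in a discrete
    mode ``expanded_mode_offset`` repeats above the constitutive allele,
    with ``expansion_sd`` its width.  ``expanded_fraction`` is the fraction
    of template molecules carrying a somatic expansion.  ``stutter_decay``
    is the per-repeat geometric decay of PCR stutter below each allele and
    ``noise_cv`` the coefficient of variation of multiplicative peak-height
    noise.
    """

    kind: str  # "tail" | "striatum" | "liver"
    constitutive_cag: int = 139
    expansion_mean: float = 0.0
    expansion_sd: float = 1.0
    expanded_mode_offset: Optional[int] = None
    expanded_fraction: float = 0.0
    stutter_decay: float = 0.15
    noise_cv: float = 0.05

    def __post_init__(self) -> None:
        if self.kind not in ("tail", "striatum", "liver"):
            raise ValueError(f"unknown tissue kind {self.kind!r}")
        if self.kind == "tail" and self.expansion_mean != 0:
            raise ValueError("tail profiles are stable: expansion_mean must be 0")
        if self.kind == "liver" and self.expanded_mode_offset is None:
            raise ValueError("liver profiles need expanded_mode_offset")
        if not 0 < self.stutter_decay < 1:
            raise ValueError("stutter_decay must be in (0, 1)")
        if not 0 <= self.expanded_fraction <= 1:
            raise ValueError("expanded_fraction must be in [0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.expansion_mean < 0 or self.expansion_sd <= 0:
            raise ValueError("expansion_mean >= 0 and expansion_sd > 0 required")


def default_profile(kind: str, constitutive_cag: int = 139) -> TissueProfile:
    """Calibrated per-tissue defaults.

    Chosen so that scored traces reproduce the qualitative tissue ordering
    (liver > striatum > tail) with instability indices in the ranges
    reported for 5-month heterozygous knock-in mice (liver around +12,
    striatum around +8, tail near 0).
    """
    if kind == "tail":
        return TissueProfile(kind="tail", constitutive_cag=constitutive_cag)
    if kind == "striatum":
        return TissueProfile(
            kind="striatum",
            constitutive_cag=constitutive_cag,
            expansion_mean=12.0,
            expansion_sd=4.0,
            expanded_fraction=0.75,
        )
    if kind == "liver":
        return TissueProfile(
            kind="liver",
            constitutive_cag=constitutive_cag,
            expansion_mean=0.0,
            expansion_sd=2.5,
            expanded_mode_offset=18,
            expanded_fraction=0.70,
        )
    raise ValueError(f"unknown tissue kind {kind!r}")


def _allele_distribution(profile: TissueProfile) -> dict[int, float]:
    """True (pre-PCR) repeat-length distribution: CAG -> probability mass."""
    c0 = profile.constitutive_cag
    f = profile.expanded_fraction
    dist = {c0: 1.0 - f}
    if profile.kind == "tail" or f == 0:
        dist[c0] = 1.0
        return dist
    if profile.kind == "striatum":
        # positive-skew expansion tail: discretised gamma over delta >= 1
        m, s = profile.expansion_mean, profile.expansion_sd
        shape = (m / s) ** 2
        scale = s**2 / m
        gamma = stats.gamma(a=shape, scale=scale)
        hi = int(math.ceil(m + 6 * s))
        deltas = np.arange(1, hi + 1)
        pmf = gamma.cdf(deltas + 0.5) - gamma.cdf(deltas - 0.5)
        pmf /= pmf.sum()
        for d, p in zip(deltas, pmf):
            dist[c0 + int(d)] = dist.get(c0 + int(d), 0.0) + f * float(p)
    else:  # liver: discrete expanded mode with a narrow gaussian width
        off, s = profile.expanded_mode_offset, profile.expansion_sd
        lo = max(1, int(off - math.ceil(4 * s)))
        hi = int(off + math.ceil(4 * s))
        deltas = np.arange(lo, hi + 1)
        pmf = stats.norm.pdf(deltas, loc=off, scale=s)
        pmf /= pmf.sum()
        for d, p in zip(deltas, pmf):
            dist[c0 + int(d)] = dist.get(c0 + int(d), 0.0) + f * float(p)
    return dist


def expected_profile(profile: TissueProfile) -> dict[int, float]:
    """Noise-free expected peak heights: alleles convolved with PCR stutter.

    Each template allele at repeat length *a* with mass *m* contributes a
    geometric stutter ladder m * decay^k at lengths a - k (k >= 1) below
    itself, truncated once the relative contribution is negligible.  The
    result is scaled so the tallest peak is ``MAIN_PEAK_HEIGHT``.
    """
    alleles = _allele_distribution(profile)
    s = profile.stutter_decay
    heights: dict[int, float] = {}
    for a, m in alleles.items():
        k = 0
        while True:
            contrib = m * s**k
            if k > 0 and contrib < _STUTTER_FLOOR * m:
                break
            pos = a - k
            if pos < 1:
                break
            heights[pos] = heights.get(pos, 0.0) + contrib
            k += 1
    peak = max(heights.values())
    return {c: h * MAIN_PEAK_HEIGHT / peak for c, h in sorted(heights.items())}


def simulate_trace(profile: TissueProfile, seed: int) -> RepeatTrace:
    """One synthetic trace: expected profile times multiplicative noise.

    Noise is lognormal with unit mean and coefficient of variation
    ``profile.noise_cv``; with ``noise_cv=0`` the trace is the expected
    profile exactly.  Deterministic for a fixed seed.
    """
    heights = expected_profile(profile)
    if profile.noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = math.sqrt(math.log(1 + profile.noise_cv**2))
        noise = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=len(heights))
        heights = {c: h * n for (c, h), n in zip(heights.items(), noise)}
    return RepeatTrace(
        peaks=heights,
        sample_id=f"sim-{profile.kind}-{seed}",
        tissue=profile.kind,
        constitutive_cag=profile.constitutive_cag,
    )


def true_index(
    profile: TissueProfile, rel_threshold: float = 0.20
) -> float:
    """Analytic instability index of the noise-free expected profile.

    Applies the same thresholding and height-normalised weighted sum to the
    expected heights directly — the recovery target that scored simulated
    traces should approach as noise vanishes.  Computed with an explicit
    loop, independently of the scoring module.
    """
    heights = expected_profile(profile)
    main_cag, main_h = None, -1.0
    for c in sorted(heights):
        if heights[c] > main_h:
            main_cag, main_h = c, heights[c]
    kept = {
        c: h for c, h in heights.items()
        if h >= rel_threshold * main_h or c == main_cag
    }
    total = sum(kept.values())
    return sum(h / total * (c - main_cag) for c, h in kept.items())


# ---------------------------------------------------------------------------
# Cohorts

#: (intercept-at-day-25 grams, gain g/day) by (chr10_background, sex); the
#: published group mean IW and WG of the wild-type weight cohorts.
_WEIGHT_PARAMS = {
    ("B6J/B6J", "female"): (10.02, 0.081),
    ("B6J/B6J", "male"): (9.22, 0.133),
    ("B6J/AJ", "female"): (13.03, 0.063),
    ("B6J/AJ", "male"): (13.92, 0.113),
}
_IW_SD = 1.8  # between-mouse SD of initial weight, g
_WG_SD = 0.014  # between-mouse SD of gain rate, g/day
_WEIGH_NOISE_SD = 0.3  # per-weighing measurement noise, g

#: DARPP-32 intensity (mean, SD) by (htt_genotype, chr10_background)
_DARPP_PARAMS = {
    ("+/+", "B6J/B6J"): (156.0, 3.7),
    ("Q111/+", "B6J/B6J"): (134.2, 7.1),
    ("+/+", "B6J/AJ"): (150.7, 7.0),
    ("Q111/+", "B6J/AJ"): (137.4, 3.7),
}

#: inclusion percentage (mean, SD) for mutant mice by chr10_background
_INCLUSION_PARAMS = {
    "B6J/B6J": (35.88, 11.45),
    "B6J/AJ": (46.69, 12.11),
}

_SECTION_NOISE_SD = 2.0  # per-section spread around the per-mouse true value
_N_SECTIONS = 3
_WEIGH_DAYS = tuple(range(21, 176, 7))  # weekly, weaning to ~25 weeks


@dataclass(frozen=True)
class CohortSpec:
    """Design of a simulated F1 cohort.

    ``n_per_cell`` animals are generated for every genotype x background x
    sex cell (the study design used five per sex, ten per genotype).
    ``darpp_params``/``inclusion_params``/``weight_params`` override the
    published-default group means and SDs; keys as in the module-level
    tables.
    """

    n_per_cell: int = 5
    seed: int = 0
    weight_params: dict = field(default_factory=lambda: dict(_WEIGHT_PARAMS))
    darpp_params: dict = field(default_factory=lambda: dict(_DARPP_PARAMS))
    inclusion_params: dict = field(default_factory=lambda: dict(_INCLUSION_PARAMS))

    def __post_init__(self) -> None:
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")


def simulate_cohort(spec: CohortSpec) -> list[MouseRecord]:
    """Generate per-mouse records for a full genotype x background x sex grid.

    Weight trajectories are linear in age (background- and sex-specific
    intercept and slope, mouse-level random effects on both, small
    per-weighing noise).  Mutant mice get a constitutive CAG drawn
    uniformly from the transmitted range and histology readouts from the
    group-specific normal distributions; DARPP-32 is simulated for all
    genotypes, inclusions only for mutants.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[MouseRecord] = []
    i = 0
    for genotype in ("+/+", "Q111/+"):
        for background in ("B6J/B6J", "B6J/AJ"):
            for sex in ("female", "male"):
                for _ in range(spec.n_per_cell):
                    i += 1
                    iw25, wg = spec.weight_params[(background, sex)]
                    b1 = rng.normal(wg, _WG_SD)
                    b0 = rng.normal(iw25, _IW_SD) - 25 * b1
                    weights = {
                        float(d): max(
                            0.0, b0 + b1 * d + rng.normal(0, _WEIGH_NOISE_SD)
                        )
                        for d in _WEIGH_DAYS
                    }
                    cag = (
                        int(rng.integers(CAG_RANGE[0], CAG_RANGE[1] + 1))
                        if genotype == "Q111/+"
                        else None
                    )
                    d_mean, d_sd = spec.darpp_params[(genotype, background)]
                    d_true = rng.normal(d_mean, d_sd)
                    darpp = tuple(
                        float(np.clip(rng.normal(d_true, _SECTION_NOISE_SD), 0, 255))
                        for _ in range(_N_SECTIONS)
                    )
                    inclusions: tuple[tuple[int, int], ...] = ()
                    if genotype == "Q111/+":
                        p_mean, p_sd = spec.inclusion_params[background]
                        p_true = float(np.clip(rng.normal(p_mean, p_sd), 0, 100))
                        sections = []
                        for _ in range(_N_SECTIONS):
                            n_cells = int(rng.integers(80, 121))
                            n_inc = int(rng.binomial(n_cells, p_true / 100))
                            sections.append((n_inc, n_cells))
                        inclusions = tuple(sections)
                    records.append(
                        MouseRecord(
                            id=f"m{i:03d}",
                            sex=sex,
                            htt_genotype=genotype,
                            chr10_background=background,
                            constitutive_cag=cag,
                            weights=weights,
                            inclusion_counts=inclusions,
                            darpp32_intensity=darpp,
                        )
                    )
    return records


# ---------------------------------------------------------------------------
# Transmissions


def simulate_transmissions(
    n: int,
    p_expand: float = 0.74,
    magnitude_sd: float = 3.0,
    seed: int = 0,
    parent_cag: int = 139,
    cross: str = "B6J",
) -> list[TransmissionEvent]:
    """Paternal transmissions with an expansion bias.

    Each transmission expands with probability ``p_expand`` and contracts
    otherwise; the magnitude of change is a discretised half-normal with
    scale ``magnitude_sd``, floored at one repeat.
    """
    if not 0 <= p_expand <= 1:
        raise ValueError("p_expand must be in [0, 1]")
    rng = np.random.default_rng(seed)
    events = []
    for _ in range(n):
        sign = 1 if rng.random() < p_expand else -1
        mag = max(1, round(abs(rng.normal(0, magnitude_sd))))
        events.append(
            TransmissionEvent(
                parent_cag=parent_cag,
                offspring_cag=parent_cag + sign * mag,
                cross=cross,
            )
        )
    return events
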