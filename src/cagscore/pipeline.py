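"""End-to-end run: peak tables + phenotype tables -> metrics -> group statistics.

The orchestration layer glues the scoring, trait-derivation and statistics
modules into one reproducible run driven by a plain config mapping (YAML
on disk).  Outputs are tab-delimited tables plus a run log recording the
package version, seed, threshold and every statistical decision taken.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_stats import compare_groups
from .instability import distance_between_modes, instability_index
from .peak_io import SizeCalibration, build_trace, group_rows, read_peak_table
from .phenotypes import DAY_FW, DAY_IW, DAY_MW, MouseRecord, trait_table
from .transmission import delta_summary, expansion_bias, read_transmissions

logger = logging.getLogger(__name__)

#: mouse-level numeric traits eligible for group comparison
TRAIT_COLUMNS = ("IW", "MW", "FW", "EWG", "FWG", "WG", "inclusion_pct", "darpp32")


@dataclass
class RunConfig:
    """Configuration for one pipeline run.  Any path may be omitted to skip
    that stage."""

    out_dir: Path
    peak_table: Optional[Path] = None
    mice_table: Optional[Path] = None
    weights_table: Optional[Path] = None
    histology_table: Optional[Path] = None
    transmissions_table: Optional[Path] = None
    calibration: SizeCalibration = dc_field(
        default_factory=lambda: SizeCalibration(anchor_cag=139, anchor_size_bp=417.0)
    )
    threshold: float = 0.20
    min_separation: int = 5
    anchor_days: tuple[float, float, float] = (DAY_IW, DAY_MW, DAY_FW)
    group_by: str = "htt_genotype"
    method: str = "auto"
    column_map: Optional[Mapping[str, str]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")
        self.out_dir = Path(self.out_dir)
        for name in (
            "peak_table", "mice_table", "weights_table",
            "histology_table", "transmissions_table",
        ):
            p = getattr(self, name)
            if p is not None:
                p = Path(p)
                setattr(self, name, p)
                if not p.exists():
                    raise FileNotFoundError(f"{name}: no such file: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cal = raw.pop("calibration", None)
        cfg = cls(**raw)
        if cal:
            cfg.calibration = SizeCalibration(**cal)
        return cfg


def score_peak_table(
    path: str | Path,
    cal: SizeCalibration,
    threshold: float = 0.20,
    min_separation: int = 5,
    column_map: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Score every sample x tissue in a peak table.

    The constitutive repeat length for each sample is taken from its tail
    trace's main allele when a tail trace is present.
    """
    rows = read_peak_table(path, column_map)
    grouped = group_rows(rows)
    # first pass: tail main alleles define per-sample constitutive CAG
    constitutive: dict[str, int] = {}
    for (sample, tissue), rws in grouped.items():
        if tissue == "tail":
            trace = build_trace(rws, cal)
            constitutive[sample] = instability_index(trace, threshold).main_allele_cag
    out = []
    for (sample, tissue), rws in grouped.items():
        trace = build_trace(rws, cal, constitutive_cag=constitutive.get(sample))
        res = instability_index(trace, threshold)
        pattern = distance_between_modes(trace, threshold, min_separation)
        out.append(
            {
                "sample": sample,
                "tissue": tissue,
                "main_allele_cag": res.main_allele_cag,
                "constitutive_cag": constitutive.get(sample, res.main_allele_cag),
                "instability_index": res.instability_index,
                "expansion_index": res.expansion_index,
                "contraction_index": res.contraction_index,
                "n_retained_peaks": len(res.retained_peaks),
                "distance_to_longest": pattern.distance_to_longest,
                "distance_between_modes": pattern.distance_between_modes,
            }
        )
    return pd.DataFrame(out).sort_values(["sample", "tissue"]).reset_index(drop=True)


def load_mouse_records(
    mice_path: str | Path,
    weights_path: Optional[str | Path] = None,
    histology_path: Optional[str | Path] = None,
) -> list[MouseRecord]:
    """Assemble MouseRecords from the tabular inputs.

    ``mice_path``: id, sex, htt_genotype, chr10_background[, constitutive_cag].
    ``weights_path``: long format id, day, grams.
    ``histology_path``: id, section[, n_inclusions, n_em48_cells][, darpp32].
    """
    mice = pd.read_csv(mice_path, sep="\t", dtype={"id": str})
    weights = (
        pd.read_csv(weights_path, sep="\t", dtype={"id": str})
        if weights_path
        else None
    )
    histo = (
        pd.read_csv(histology_path, sep="\t", dtype={"id": str})
        if histology_path
        else None
    )
    records = []
    for _, m in mice.iterrows():
        wmap: dict[float, float] = {}
        if weights is not None:
            sub = weights[weights["id"] == m["id"]]
            wmap = dict(zip(sub["day"].astype(float), sub["grams"].astype(float)))
        inclusions: tuple = ()
        darpp: tuple = ()
        if histo is not None:
            sub = histo[histo["id"] == m["id"]]
            if {"n_inclusions", "n_em48_cells"} <= set(sub.columns):
                ok = sub.dropna(subset=["n_inclusions", "n_em48_cells"])
                inclusions = tuple(
                    (int(i), int(n))
                    for i, n in zip(ok["n_inclusions"], ok["n_em48_cells"])
                )
            if "darpp32" in sub.columns:
                darpp = tuple(float(v) for v in sub["darpp32"].dropna())
        cag = m.get("constitutive_cag")
        records.append(
            MouseRecord(
                id=str(m["id"]),
                sex=str(m["sex"]),
                htt_genotype=str(m["htt_genotype"]),
                chr10_background=str(m["chr10_background"]),
                constitutive_cag=int(cag) if pd.notna(cag) else None,
                weights=wmap,
                inclusion_counts=inclusions,
                darpp32_intensity=darpp,
            )
        )
    return records


def compare_trait_table(
    traits: pd.DataFrame,
    group_by: str,
    method: str = "auto",
    columns: Sequence[str] = TRAIT_COLUMNS,
) -> pd.DataFrame:
    """Pairwise two-group comparison of every trait column.

    The ``group_by`` column must define exactly two groups; traits with
    fewer than two non-missing values in either group are skipped.
    """
    levels = sorted(traits[group_by].dropna().unique())
    if len(levels) != 2:
        raise ValueError(
            f"group_by={group_by!r} defines {len(levels)} groups, need exactly 2"
        )
    rows = []
    for col in columns:
        if col not in traits.columns:
            continue
        a = traits.loc[traits[group_by] == levels[0], col].dropna().to_numpy()
        b = traits.loc[traits[group_by] == levels[1], col].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            continue
        cmp = compare_groups(a, b, method=method, labels=(str(levels[0]), str(levels[1])))
        rows.append(
            {
                "trait": col,
                "group_a": cmp.group_labels[0],
                "group_b": cmp.group_labels[1],
                "n_a": cmp.n_a,
                "n_b": cmp.n_b,
                "mean_a": cmp.mean_a,
                "mean_b": cmp.mean_b,
                "sd_a": cmp.sd_a,
                "sd_b": cmp.sd_b,
                "test_used": cmp.test_used,
                "statistic": cmp.statistic,
                "p_value": cmp.p_value,
                "shapiro_p_a": cmp.normality_p[0],
                "shapiro_p_b": cmp.normality_p[1],
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute every configured stage; return the paths written.

    Stages: trace scoring (peak table), trait derivation (mouse tables),
    group comparison, transmission summary.  A failing stage raises with
    the stage named; identical config and seed give identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    log_lines = [
        f"cagscore {__version__}",
        f"seed={config.seed} threshold={config.threshold} "
        f"min_separation={config.min_separation}",
        f"calibration: anchor_cag={config.calibration.anchor_cag} "
        f"anchor_size_bp={config.calibration.anchor_size_bp} "
        f"bp_per_repeat={config.calibration.bp_per_repeat}",
    ]

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    traits_df = None
    if config.peak_table is not None:
        metrics = _stage(
            "instability",
            lambda: score_peak_table(
                config.peak_table, config.calibration, config.threshold,
                config.min_separation, config.column_map,
            ),
        )
        p = out / "trace_metrics.tsv"
        metrics.to_csv(p, sep="\t", index=False, float_format="%.6g")
        written["trace_metrics"] = p
        log_lines.append(f"scored {len(metrics)} traces from {config.peak_table}")

    if config.mice_table is not None:
        records = _stage(
            "phenotypes",
            lambda: load_mouse_records(
                config.mice_table, config.weights_table, config.histology_table
            ),
        )
        d_iw, d_mw, d_fw = config.anchor_days
        traits_df = _stage(
            "phenotypes", lambda: trait_table(records, d_iw, d_mw, d_fw)
        )
        p = out / "traits.tsv"
        traits_df.to_csv(p, sep="\t", index=False, float_format="%.6g")
        written["traits"] = p
        log_lines.append(f"derived traits for {len(traits_df)} mice")

    if traits_df is not None:
        comparisons = _stage(
            "cohort_stats",
            lambda: compare_trait_table(traits_df, config.group_by, config.method),
        )
        p = out / "comparisons.tsv"
        comparisons.to_csv(p, sep="\t", index=False, float_format="%.6g")
        written["comparisons"] = p
        for _, r in comparisons.iterrows():
            log_lines.append(
                f"compared {r['trait']} by {config.group_by}: test={r['test_used']} "
                f"(shapiro_p={r['shapiro_p_a']:.3g}/{r['shapiro_p_b']:.3g}) "
                f"p={r['p_value']:.4g}"
            )

    if config.transmissions_table is not None:
        events = _stage(
            "transmission", lambda: read_transmissions(config.transmissions_table)
        )
        summary = delta_summary(events)
        biases = []
        for cross in summary["cross"]:
            sub = [e for e in events if e.cross == cross]
            biases.append(expansion_bias(sub))
        summary["expansion_bias_pct"] = biases
        p = out / "transmission_summary.tsv"
        summary.to_csv(p, sep="\t", index=False, float_format="%.6g")
        written["transmission_summary"] = p
        log_lines.append(f"summarised {len(events)} transmissions")

    log_path = out / "run_log.txt"
    log_path.write_text("\n".join(log_lines) + "\n")
    written["run_log"] = log_path
    for line in log_lines:
        logger.info("%s", line)
    return written
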