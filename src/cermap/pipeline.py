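"""End-to-end experiment: generate → quantify → score → compare → report.

One configuration describes a panel of constructs, a shared cell geometry
and camera model, a per-construct cohort size, and a reference construct.
Running it produces, under ``output_dir``:

* ``cells.csv`` — one row per cell (truth, measured means, CER, QC, call)
* ``summary.csv`` — per-construct call counts, box statistics, normality flag
* ``comparisons.csv`` — each construct vs. the reference: exact Wilcoxon p
  on the CER distributions and Fisher's exact p on positive vs. rest counts,
  with significance stars (* p<0.05, ** p<0.01, *** p<0.001)
* ``boxplot.png`` — CER box-and-whisker panel with the positivity threshold
* ``run_log.json`` — seed, config hash, package version, decision parameters

All randomness descends from the single config seed, so a rerun with the
same config reproduces the report byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .catalog import load_catalog, profile_for_target_cer
from .quantify import CERMeasurement, NoCellError, quantify_cell
from .score import DEFAULT_CER_THRESHOLD, Call, CohortSummary, classify_cell, summarize_cohort
from .stats import ContingencyTable2x2, anderson_darling_normal, fisher_exact, wilcoxon_exact
from .synthgen import CellGeometry, LocalizationProfile, NoiseModel, SyntheticCell, generate_cohort

__all__ = ["ExperimentConfig", "ExperimentReport", "run_experiment", "quantify_synthetic_cell"]

logger = logging.getLogger("cermap")


@dataclass
class ExperimentConfig:
    profiles: list[LocalizationProfile]
    n_cells: int = 12
    geometry: CellGeometry = field(default_factory=CellGeometry)
    noise: NoiseModel = field(default_factory=NoiseModel)
    reference_construct: str = ""
    cer_threshold: float = DEFAULT_CER_THRESHOLD
    seed: int = 0
    output_dir: str | Path | None = None
    holm_adjust: bool = False

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        names = [p.name for p in self.profiles]
        if len(set(names)) != len(names):
            raise ValueError("profile names must be unique")
        if not self.reference_construct:
            self.reference_construct = names[0]
        if self.reference_construct not in names:
            raise ValueError(f"reference construct {self.reference_construct!r} not in profiles")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        """Build a config from a YAML file.

        Constructs may be given as catalogue names (``constructs: [WT_1_433,
        GFP]``) or as explicit profiles with a ``target_cer`` to calibrate
        or a literal ``chrom_enrich``.
        """
        raw = yaml.safe_load(Path(path).read_text())
        geometry = CellGeometry(**raw.get("geometry", {}))
        noise = NoiseModel(**raw.get("noise", {}))
        profiles: list[LocalizationProfile] = []
        if "constructs" in raw:
            catalog = load_catalog(geometry=geometry, names=list(raw["constructs"]))
            profiles += [catalog[name] for name in raw["constructs"]]
        for entry in raw.get("profiles", []):
            entry = dict(entry)
            name = entry.pop("name")
            if "target_cer" in entry:
                profiles.append(profile_for_target_cer(name, entry.pop("target_cer"), geometry, **entry))
            else:
                profiles.append(LocalizationProfile(name=name, **entry))
        kwargs = {
            k: raw[k]
            for k in ("n_cells", "reference_construct", "cer_threshold", "seed", "output_dir", "holm_adjust")
            if k in raw
        }
        return cls(profiles=profiles, geometry=geometry, noise=noise, **kwargs)


@dataclass
class ExperimentReport:
    cells: pd.DataFrame
    summaries: dict[str, CohortSummary]
    comparisons: pd.DataFrame
    summary_table: pd.DataFrame
    run_log: dict
    output_dir: Path | None


def quantify_synthetic_cell(cell: SyntheticCell, roi: str = "hand") -> CERMeasurement:
    """Quantify a generated cell with its own annotations.

    ``roi="hand"`` uses the emulated hand-drawn plate ROI (the realistic
    path); ``roi="truth"`` uses the ground-truth plate mask (for oracle
    checks of the measurement chain itself).
    """
    mask = cell.chrom_roi if roi == "hand" else cell.chrom_mask_truth
    m = quantify_cell(cell.fluor_image, mask, cell.background_mask, cell_id=cell.cell_id)
    m.meta.update(true_cer=cell.true_cer, saturated=cell.saturated, roi=roi)
    return m


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _holm(pvals: list[float]) -> list[float]:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


def _config_hash(config: ExperimentConfig) -> str:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            # output_dir does not affect the science; keep the hash stable
            return {f.name: enc(getattr(obj, f.name))
                    for f in dataclasses.fields(obj) if f.name != "output_dir"}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        if isinstance(obj, Path):
            return str(obj)
        return obj
    payload = json.dumps(enc(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Run the full multi-construct experiment described by ``config``."""
    ss = np.random.SeedSequence(config.seed)
    cohort_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(config.profiles))]

    rows = []
    summaries: dict[str, CohortSummary] = {}
    cohort_cells: dict[str, list[tuple[CERMeasurement, bool]]] = {}
    for profile, cohort_seed in zip(config.profiles, cohort_seeds):
        logger.info("generating cohort %s (n=%d, seed=%d)", profile.name, config.n_cells, cohort_seed)
        cells = generate_cohort(profile, config.n_cells, config.geometry, config.noise, seed=cohort_seed)
        scored = []
        for cell in cells:
            try:
                m = quantify_synthetic_cell(cell)
            except NoCellError:
                # reporter too dim to segment: unscorable underexpressor
                m = CERMeasurement(
                    cell_id=cell.cell_id, chrom_mean=math.nan, cell_mean=0.0,
                    background=None, cer=math.nan, qc_pass=False,
                    meta={"true_cer": cell.true_cer, "failure": "no cell detected"},
                )
            except Exception as exc:
                raise RuntimeError(f"construct {profile.name}, cell {cell.cell_id}: {exc}") from exc
            call = classify_cell(m, cell.plate_defined, config.cer_threshold)
            scored.append((m, cell.plate_defined))
            rows.append(
                {
                    "construct": profile.name,
                    "cell_id": cell.cell_id,
                    "seed": cell.seed,
                    "expression": cell.expression,
                    "true_cer": cell.true_cer,
                    "plate_defined": cell.plate_defined,
                    "saturated": cell.saturated,
                    "bg_mean": m.background.mean if m.background else math.nan,
                    "bg_sd": m.background.sd if m.background else math.nan,
                    "chrom_mean": m.chrom_mean,
                    "cell_mean": m.cell_mean,
                    "cer": m.cer,
                    "qc_pass": m.qc_pass,
                    "call": call.call.value,
                    "reason": call.reason,
                }
            )
        cohort_cells[profile.name] = scored
        summaries[profile.name] = summarize_cohort(scored, profile.name, config.cer_threshold)

    cells_df = pd.DataFrame(rows)

    summary_rows = []
    for name, s in summaries.items():
        normal = None
        if len(s.cer_values) >= 8:
            normal = anderson_darling_normal(s.cer_values)
        summary_rows.append(
            {
                "construct": name,
                "n_total": s.n_total,
                "n_positive": s.n_positive,
                "n_absent": s.n_absent,
                "n_cannot_call": s.n_cannot_call,
                "n_cer": len(s.cer_values),
                "cer_mean": s.box.mean if s.box else math.nan,
                "cer_median": s.box.median if s.box else math.nan,
                "cer_q1": s.box.q1 if s.box else math.nan,
                "cer_q3": s.box.q3 if s.box else math.nan,
                "cer_min": s.box.min if s.box else math.nan,
                "cer_max": s.box.max if s.box else math.nan,
                "ad_a2_star": normal.statistic if normal else math.nan,
                "ad_p": normal.p_value if normal else math.nan,
                "normal_at_005": (not normal.details["reject_at_005"]) if normal else None,
            }
        )
    summary_df = pd.DataFrame(summary_rows)

    ref = config.reference_construct
    ref_summary = summaries[ref]
    comp_rows = []
    for name, s in summaries.items():
        if name == ref:
            continue
        w = wilcoxon_exact(s.cer_values, ref_summary.cer_values) if s.cer_values and ref_summary.cer_values else None
        table = ContingencyTable2x2(
            a=s.n_positive, b=s.n_absent + s.n_cannot_call,
            c=ref_summary.n_positive, d=ref_summary.n_absent + ref_summary.n_cannot_call,
        )
        f = fisher_exact(table)
        comp_rows.append(
            {
                "construct": name,
                "reference": ref,
                "wilcoxon_W": w.statistic if w else math.nan,
                "wilcoxon_p": w.p_value if w else math.nan,
                "wilcoxon_stars": _stars(w.p_value) if w else "",
                "fisher_odds": f.statistic,
                "fisher_p": f.p_value,
                "fisher_stars": _stars(f.p_value),
            }
        )
    comp_df = pd.DataFrame(comp_rows)
    if config.holm_adjust and not comp_df.empty:
        comp_df["wilcoxon_p_holm"] = _holm(comp_df["wilcoxon_p"].tolist())
        comp_df["fisher_p_holm"] = _holm(comp_df["fisher_p"].tolist())

    run_log = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "n_cells": config.n_cells,
        "cer_threshold": config.cer_threshold,
        "qc_window": [50.0, 500.0],
        "qc_window_inclusive": True,
        "segmentation_threshold_n_sd": 12.0,
        "quartile_method": "tukey_hinges",
        "two_sided_convention": {
            "fisher": "summed smaller probabilities",
            "wilcoxon": "doubled smaller tail, capped at 1",
        },
        "holm_adjust": config.holm_adjust,
        "reference_construct": ref,
        "constructs": [p.name for p in config.profiles],
        "cohort_seeds": cohort_seeds,
    }

    out = Path(config.output_dir) if config.output_dir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        cells_df.to_csv(out / "cells.csv", index=False, float_format="%.10g")
        summary_df.to_csv(out / "summary.csv", index=False, float_format="%.10g")
        comp_df.to_csv(out / "comparisons.csv", index=False, float_format="%.10g")
        (out / "run_log.json").write_text(json.dumps(run_log, indent=2, sort_keys=True))
        _boxplot(summaries, config.cer_threshold, out / "boxplot.png")
        logger.info("report written to %s", out)

    return ExperimentReport(cells_df, summaries, comp_df, summary_df, run_log, out)


def _boxplot(summaries: dict[str, CohortSummary], threshold: float, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    names = [n for n, s in summaries.items() if s.cer_values]
    fig, ax = plt.subplots(figsize=(max(4, 0.9 * len(names) + 1.5), 4))
    data = [summaries[n].cer_values for n in names]
    ax.boxplot(data, tick_labels=names, whis=(0, 100), showmeans=True,
               meanprops={"marker": "D", "markerfacecolor": "black", "markeredgecolor": "black"})
    ax.axhline(threshold, color="red", linestyle=":", label=f"threshold {threshold:g}")
    ax.set_ylabel("chromosome enrichment ratio")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120, metadata={"Software": "cermap"})
    plt.close(fig)
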