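"""End-to-end reproducible run: simulate -> footprint -> threshold fit ->
diet quality -> report.

A run is described by a :class:`RunConfig` (YAML/JSON-serializable), executes
stage by stage with per-stage logging, and writes every artifact into a fresh
run directory together with a manifest (seed, config hash, package version,
artifact checksums). Identical config + seed give byte-identical artifacts;
the directory name carries a timestamp so runs never overwrite each other.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .accounting import (
    EmissionFactorTable,
    annualize,
    categorize,
    filter_and_winsorize,
    footprint,
    group_mean_shares,
)
from .diet_quality import (
    default_ranges,
    deviation_frame,
    group_difference_test,
    group_regression,
    per_capita_daily,
    ranges_from_csv,
)
from .reference import ANIMAL_SUBCATEGORIES
from .synthetic import SyntheticConfig, generate_panel, generate_recall_records, synthetic_factor_table
from .threshold import (
    ThresholdModel,
    estimate_threshold,
    fit_report,
    format_report,
    threshold_number_test,
)

__all__ = ["RunConfig", "run", "PipelineError"]

log = logging.getLogger("foodcarbon.pipeline")

#: six-category aggregation used for diet-quality scoring
QUALITY_CATEGORIES = ("cereal", "tuber", "vegetables", "fruit", "animal", "dairy")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one input source is required: a ``panel_path`` CSV (columns as
    written by the synthetic generator) or a ``synthetic`` config. Footprints
    are recomputed from recall records when these are available (always, on
    the synthetic path).
    """

    synthetic: SyntheticConfig | None = None
    panel_path: str | None = None
    recall_path: str | None = None
    factors_path: str | None = None
    ranges_path: str | None = None
    out_dir: str = "runs"
    n_boot: int = 200
    max_thresholds: int = 3
    alpha: float = 0.05
    seed: int = 0
    trim: float = 0.01
    min_share: float = 0.05
    max_grid: int | None = None
    bootstrap_scheme: str = "household"
    winsor_limits: float = 0.01
    model: ThresholdModel = field(default_factory=ThresholdModel)

    def __post_init__(self) -> None:
        if self.synthetic is None and self.panel_path is None:
            raise ValueError("need either a synthetic config or a panel_path")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synthetic"] = self.synthetic.to_dict() if self.synthetic else None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("synthetic"):
            d["synthetic"] = SyntheticConfig.from_dict(d["synthetic"])
        if d.get("model"):
            m = dict(d["model"])
            if "controls" in m:
                m["controls"] = tuple(m["controls"])
            d["model"] = ThresholdModel(**m)
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.12g")


def run(config: RunConfig, run_name: str | None = None) -> Path:
    """Execute the pipeline; returns the run directory."""
    stamp = run_name or datetime.now(timezone.utc).strftime("run-%Y%m%dT%H%M%S")
    run_dir = Path(config.out_dir) / stamp
    i = 0
    while run_dir.exists():  # never overwrite an earlier run
        i += 1
        run_dir = Path(config.out_dir) / f"{stamp}-{i}"
    run_dir.mkdir(parents=True)
    artifacts: dict[str, Path] = {}
    stage_times: dict[str, float] = {}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            log.info("stage %s ...", name)
            try:
                out = fn()
            except Exception as e:  # noqa: BLE001 - re-raised with stage name
                raise PipelineError(f"stage {name!r} failed: {e}") from e
            stage_times[name] = time.perf_counter() - t0
            log.info("stage %s done in %.2fs", name, stage_times[name])
            return out

        return deco

    # -- inputs --------------------------------------------------------------
    @stage("load")
    def _inputs():
        if config.synthetic is not None:
            syn = SyntheticConfig.from_dict({**config.synthetic.to_dict(),
                                             "seed": config.seed})
            panel = generate_panel(syn)
            recall = generate_recall_records(syn, panel)
            factors = (
                EmissionFactorTable.from_csv(config.factors_path)
                if config.factors_path
                else synthetic_factor_table()
            )
        else:
            panel = pd.read_csv(config.panel_path)
            recall = pd.read_csv(config.recall_path) if config.recall_path else None
            if config.factors_path is None and recall is not None:
                raise ValueError("recall records supplied without a factor table")
            factors = (
                EmissionFactorTable.from_csv(config.factors_path)
                if config.factors_path
                else None
            )
        return panel, recall, factors

    panel, recall, factors = _inputs

    # -- accounting ----------------------------------------------------------
    @stage("footprint")
    def _footprint():
        if recall is None:
            if "ghg" not in panel.columns:
                raise ValueError("panel has no ghg column and no recall records")
            return panel, None
        annual = annualize(recall)
        ghg = footprint(annual, factors)
        p = panel.drop(columns=["ghg"], errors="ignore").merge(
            ghg.reset_index(), on=["household_id", "wave"], how="left"
        )
        cats = categorize(annual, factors)
        return p, cats

    panel_acc, cats = _footprint

    @stage("filter")
    def _filter():
        return filter_and_winsorize(
            panel_acc, limits=config.winsor_limits, enforce_balance=True
        )

    filtered = _filter
    _write_csv(filtered, run_dir / "panel.csv")
    artifacts["panel"] = run_dir / "panel.csv"

    # -- threshold regression ------------------------------------------------
    @stage("fit")
    def _fit():
        fit = estimate_threshold(
            filtered,
            config.model,
            trim=config.trim,
            min_share=config.min_share,
            max_grid=config.max_grid,
            alpha=config.alpha,
        )
        test = threshold_number_test(
            filtered,
            config.model,
            n_boot=config.n_boot,
            max_thresholds=config.max_thresholds,
            seed=config.seed,
            scheme=config.bootstrap_scheme,
            trim=config.trim,
            min_share=config.min_share,
            max_grid=config.max_grid,
        )
        return fit, test

    fit, test = _fit
    (run_dir / "fit.json").write_text(json.dumps(fit.to_dict(), indent=2))
    (run_dir / "threshold_tests.json").write_text(json.dumps(test.to_dict(), indent=2))
    _write_csv(fit.lr_curve, run_dir / "lr_curve.csv")
    _write_csv(fit_report(fit, test), run_dir / "report.csv")
    (run_dir / "report.txt").write_text(format_report(fit, test))
    for k in ("fit.json", "threshold_tests.json", "lr_curve.csv",
              "report.csv", "report.txt"):
        artifacts[k] = run_dir / k

    # -- diet quality --------------------------------------------------------
    @stage("quality")
    def _quality():
        if cats is None:
            return None
        ranges = (
            ranges_from_csv(config.ranges_path)
            if config.ranges_path
            else default_ranges()
        )
        keep_cols = list(
            dict.fromkeys(
                ["household_id", "wave", "hhinc", "hhsize", "province_id",
                 *config.model.control_names]
            )
        )
        df = cats.merge(
            filtered[keep_cols], on=["household_id", "wave"], how="inner"
        )
        gamma = fit.gamma_hat
        df["group"] = np.where(df["hhinc"] <= gamma, "low", "high")

        # per-capita daily g by quality category
        for c in QUALITY_CATEGORIES:
            df[f"{c}_gday"] = per_capita_daily(df[f"{c}_kg"], df["hhsize"])
        daily = df[[f"{c}_gday" for c in QUALITY_CATEGORIES]].rename(
            columns=lambda s: s.removesuffix("_gday")
        )
        dev = deviation_frame(daily, ranges)
        for c in QUALITY_CATEGORIES:
            df[f"{c}_dev"] = dev[f"{c}_dev"]
            df[f"{c}_adequacy"] = dev[f"{c}_adequacy"]

        # Table-2 analogue: per-capita annual amounts and share conventions
        cons_rows = []
        for gname, gdf in df.groupby("group"):
            percap = {
                c: float((gdf[f"{c}_kg"] / gdf["hhsize"]).mean())
                for c in [*QUALITY_CATEGORIES, *ANIMAL_SUBCATEGORIES]
            }
            percap["overall"] = float((gdf["total_kg"] / gdf["hhsize"]).mean())
            shares_rm = group_mean_shares(gdf, "ratio_of_means")
            shares_ms = group_mean_shares(gdf, "mean_of_shares")
            for c, v in percap.items():
                cons_rows.append(
                    {
                        "group": gname,
                        "category": c,
                        "per_capita_kg": v,
                        "share_ratio_of_means_pct": (
                            float(shares_rm.get(c, np.nan))
                        ),
                        "share_mean_of_shares_pct": (
                            float(shares_ms.get(c, np.nan))
                        ),
                    }
                )
        consumption = pd.DataFrame(cons_rows)

        # group-difference tests on per-capita amounts
        diff_rows = []
        for c in [*QUALITY_CATEGORIES, *ANIMAL_SUBCATEGORIES]:
            res = group_difference_test(
                df[f"{c}_kg"] / df["hhsize"], df["group"], df["province_id"]
            )
            diff_rows.append({"category": c, **{k: res[k] for k in
                                                ("diff", "t", "p", "degenerate")}})
        diffs = pd.DataFrame(diff_rows)

        # Table-4 analogue: adequacy rates
        adeq_rows = []
        for gname, gdf in df.groupby("group"):
            for c in QUALITY_CATEGORIES:
                adeq_rows.append(
                    {
                        "group": gname,
                        "category": c,
                        "mean_gday": float(gdf[f"{c}_gday"].mean()),
                        "insufficient_pct": float(
                            (gdf[f"{c}_adequacy"] == "insufficient").mean() * 100
                        ),
                        "excess_pct": float(
                            (gdf[f"{c}_adequacy"] == "excess").mean() * 100
                        ),
                        "mean_deviation": float(gdf[f"{c}_dev"].mean()),
                    }
                )
        adequacy = pd.DataFrame(adeq_rows)

        # grouped income regressions: amounts, shares, deviations
        reg_frames = []
        outcomes = (
            [("amount", "total_kg")]
            + [("amount", f"{c}_kg") for c in QUALITY_CATEGORIES]
            + [("share", f"{c}_pct") for c in QUALITY_CATEGORIES]
            + [("deviation", f"{c}_dev") for c in QUALITY_CATEGORIES]
        )
        for kind, col in outcomes:
            try:
                r = group_regression(df, col, gamma, config.model)
            except ValueError as e:
                log.warning("skipping %s: %s", col, e)
                continue
            r.insert(0, "kind", kind)
            reg_frames.append(r)
        regs = pd.concat(reg_frames, ignore_index=True)
        return consumption, diffs, adequacy, regs

    quality = _quality
    if quality is not None:
        consumption, diffs, adequacy, regs = quality
        for name, df_ in (
            ("consumption_by_group", consumption),
            ("group_differences", diffs),
            ("adequacy_by_group", adequacy),
            ("income_effects", regs),
        ):
            _write_csv(df_, run_dir / f"{name}.csv")
            artifacts[name] = run_dir / f"{name}.csv"

    # -- manifest ------------------------------------------------------------
    cfg_dict = config.to_dict()
    cfg_json = json.dumps(cfg_dict, sort_keys=True, default=str)
    manifest = {
        "package": "foodcarbon",
        "version": __version__,
        "seed": config.seed,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "n_obs_used": int(fit.n_obs),
        "artifacts": {k: _sha256(p) for k, p in artifacts.items()},
    }
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    # wall times are informational only and live outside the manifest so that
    # identical config+seed runs produce identical manifests
    (run_dir / "timings.json").write_text(
        json.dumps({k: round(v, 3) for k, v in stage_times.items()}, indent=2)
    )
    return run_dir
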