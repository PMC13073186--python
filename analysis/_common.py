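"""Shared data loading for the numbered analysis scripts.

All scripts analyse the same deterministic synthetic panel (seed 1, default
study-scale conditions: 2072 households over the 2004-2011 waves). Generated
snapshots are cached under scratch/ so each script can run standalone.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from foodcarbon.accounting import annualize, categorize, filter_and_winsorize, footprint
from foodcarbon.synthetic import (
    SyntheticConfig,
    generate_panel,
    generate_recall_records,
    synthetic_factor_table,
)

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"
SEED = 1

CONFIG = SyntheticConfig(seed=SEED)


def load_panel() -> pd.DataFrame:
    path = SCRATCH / "panel.csv"
    if path.exists():
        return pd.read_csv(path)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    panel = generate_panel(CONFIG)
    panel.to_csv(path, index=False)
    return panel


def load_recall() -> pd.DataFrame:
    path = SCRATCH / "recall.csv"
    if path.exists():
        return pd.read_csv(path)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    rec = generate_recall_records(CONFIG, load_panel())
    rec.to_csv(path, index=False)
    return rec


def load_accounted_panel() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Panel with ghg recomputed through the accounting chain, plus the
    per-category annual amounts; filtered and winsorized."""
    panel = load_panel()
    annual = annualize(load_recall())
    factors = synthetic_factor_table()
    ghg = footprint(annual, factors)
    acc = panel.drop(columns=["ghg"]).merge(
        ghg.reset_index(), on=["household_id", "wave"]
    )
    filtered = filter_and_winsorize(acc, enforce_balance=True)
    cats = categorize(annual, factors)
    return filtered, cats


def write_result(df: pd.DataFrame, name: str) -> Path:
    RESULTS.mkdir(exist_ok=True)
    path = RESULTS / name
    df.to_csv(path, index=False, float_format="%.6g")
    return path
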