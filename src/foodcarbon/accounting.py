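"""Footprint accounting: dietary-recall annualization, CO2eq footprints,
category amounts/shares, and the study sample filters.

The accounting chain is

    recall records (kg over a 72 h window)
      -> annual household consumption (kg/year)            annualize
      -> tons CO2eq/year via median LCA factors            footprint
      -> per-category amounts and shares                   categorize

plus the panel-level sample filters (drop negative incomes, two-sided 1%
winsorization of income and emissions, optional balanced-panel restriction).

Units: food amounts in kg; emission factors in kg CO2eq per kg; household
emissions in tons CO2eq per year; income in CPI-adjusted 10,000-yuan units.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import mstats

from .reference import ANIMAL_SUBCATEGORIES, CATEGORIES, PRINTED_FACTORS

__all__ = [
    "EmissionFactorTable",
    "UnmappedItemError",
    "annualize",
    "footprint",
    "categorize",
    "filter_and_winsorize",
    "winsorize_series",
]

HOURS_PER_YEAR = 365.0 * 24.0


class UnmappedItemError(KeyError):
    """A consumed item has no entry in the emission-factor table."""


@dataclass(frozen=True)
class EmissionFactorTable:
    """Food item -> (category, kg CO2eq per kg) mapping with a provenance tag.

    The default table carries exactly the seven median LCA factors the study
    prints (beef 51.7, pork 9.8, poultry 7.8, eggs 4.2, milk 2.3, wheat 1.3,
    rice 3.1). Plant items whose factors are described only as "below
    1 kg CO2eq/kg" (vegetables, fruit) have no silent default: they must be
    supplied explicitly via ``with_items`` or the ``plant_placeholder``
    argument of :meth:`default`, otherwise footprints would be biased by an
    invented constant.
    """

    factors: dict[str, float]
    categories: dict[str, str]
    provenance: str = "user"

    def __post_init__(self) -> None:
        if set(self.factors) != set(self.categories):
            raise ValueError("factor and category maps must cover the same items")
        for item, f in self.factors.items():
            if f < 0:
                raise ValueError(f"negative emission factor for {item!r}")
        bad = {c for c in self.categories.values() if c not in CATEGORIES}
        if bad:
            raise ValueError(f"unknown categories: {sorted(bad)}; expected {CATEGORIES}")

    # -- construction --------------------------------------------------------
    @classmethod
    def default(cls, plant_placeholder: float | None = None) -> "EmissionFactorTable":
        """The seven printed median factors, optionally extended with an
        explicit placeholder factor for vegetables and fruit.
        """
        factors = {k: v for k, (_, v) in PRINTED_FACTORS.items()}
        cats = {k: c for k, (c, _) in PRINTED_FACTORS.items()}
        prov = "study medians"
        if plant_placeholder is not None:
            if plant_placeholder < 0:
                raise ValueError("plant_placeholder must be >= 0")
            factors.update(vegetables=plant_placeholder, fruit=plant_placeholder)
            cats.update(vegetables="vegetables", fruit="fruit")
            prov += f" + plant placeholder {plant_placeholder}"
        return cls(factors, cats, prov)

    def with_items(self, items: dict[str, tuple[str, float]]) -> "EmissionFactorTable":
        """Return a new table extended/overridden with ``item: (category, factor)``."""
        factors = dict(self.factors)
        cats = dict(self.categories)
        for item, (cat, f) in items.items():
            factors[item] = f
            cats[item] = cat
        return EmissionFactorTable(factors, cats, self.provenance + " + user items")

    @classmethod
    def from_csv(cls, path: str | Path, provenance: str | None = None) -> "EmissionFactorTable":
        df = pd.read_csv(path, comment="#")
        req = {"item", "category", "factor"}
        if not req.issubset(df.columns):
            raise ValueError(f"factor CSV needs columns {sorted(req)}")
        return cls(
            dict(zip(df["item"], df["factor"].astype(float))),
            dict(zip(df["item"], df["category"])),
            provenance or str(path),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "EmissionFactorTable":
        data = json.loads(Path(path).read_text())
        return cls(
            {k: float(v["factor"]) for k, v in data["items"].items()},
            {k: v["category"] for k, v in data["items"].items()},
            data.get("provenance", str(path)),
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "item": list(self.factors),
                "category": [self.categories[i] for i in self.factors],
                "factor": [self.factors[i] for i in self.factors],
            }
        ).to_csv(path, index=False)

    # -- queries -------------------------------------------------------------
    def factor(self, item: str) -> float:
        try:
            return self.factors[item]
        except KeyError:
            raise UnmappedItemError(
                f"item {item!r} has no emission factor; supply it explicitly "
                "(plant items have no silent default)"
            ) from None

    def category(self, item: str) -> str:
        try:
            return self.categories[item]
        except KeyError:
            raise UnmappedItemError(f"item {item!r} has no category mapping") from None

    @property
    def items(self) -> list[str]:
        return list(self.factors)


# ---------------------------------------------------------------------------
# Recall -> annual consumption
# ---------------------------------------------------------------------------

def annualize(records: pd.DataFrame, window_hours: float = 72.0) -> pd.DataFrame:
    """Scale recall-window amounts (kg) to annual consumption (kg/year).

    ``records`` needs columns ``household_id, wave, item, amount`` and may
    carry a per-row ``window`` column (hours) overriding ``window_hours``.
    For the standard 72 h dietary recall the factor is 365*24/72 = 365/3.
    """
    out = records.copy()
    window = out["window"] if "window" in out.columns else pd.Series(
        window_hours, index=out.index
    )
    if (np.asarray(window) <= 0).any():
        raise ValueError("recall window must be positive")
    if (out["amount"] < 0).any():
        raise ValueError("recall amounts must be non-negative")
    out["annual_kg"] = out["amount"] * (HOURS_PER_YEAR / np.asarray(window, dtype=float))
    return out[["household_id", "wave", "item", "annual_kg"]]


# ---------------------------------------------------------------------------
# Annual consumption -> footprint
# ---------------------------------------------------------------------------

def footprint(
    annual: pd.DataFrame,
    factors: EmissionFactorTable,
    on_unmapped: str = "error",
) -> pd.Series:
    """Tons CO2eq/year per household-wave.

    ghg = sum_items annual_kg * factor / 1000. Additive over items, hence
    over categories; weakly increasing in every amount.

    on_unmapped: "error" (default, strict — silent zeros would bias the
    footprint downward) or "drop" (exclude the item with a warning).
    """
    if annual.empty:
        return pd.Series(dtype=float, name="ghg")
    unmapped = sorted(set(annual["item"]) - set(factors.factors))
    if unmapped:
        if on_unmapped == "error":
            raise UnmappedItemError(
                f"items without emission factors: {unmapped}"
            )
        elif on_unmapped == "drop":
            warnings.warn(
                f"dropping items without emission factors: {unmapped}",
                stacklevel=2,
            )
            annual = annual[~annual["item"].isin(unmapped)]
        else:
            raise ValueError("on_unmapped must be 'error' or 'drop'")
    f = annual["item"].map(factors.factors).astype(float)
    kg_co2 = annual["annual_kg"] * f
    ghg = kg_co2.groupby(
        [annual["household_id"], annual["wave"]], sort=True
    ).sum() / 1000.0
    ghg.name = "ghg"
    return ghg


# ---------------------------------------------------------------------------
# Category amounts and shares
# ---------------------------------------------------------------------------

def categorize(
    annual: pd.DataFrame,
    factors: EmissionFactorTable,
    on_unmapped: str = "error",
) -> pd.DataFrame:
    """Per household-wave category amounts (kg/year) and percentage shares.

    Returns one row per household-wave with one ``<cat>_kg`` and one
    ``<cat>_pct`` column per category, a ``total_kg`` column, and the
    composite ``animal_kg``/``animal_pct`` (livestock + poultry + eggs +
    aquatic). Shares are within-household percentages summing to 100 whenever
    the total is positive; rows with zero total get NaN shares and
    ``shares_defined = False`` — undefined, not fabricated.
    """
    unmapped = sorted(set(annual["item"]) - set(factors.categories))
    if unmapped:
        if on_unmapped == "error":
            raise UnmappedItemError(f"items without category mapping: {unmapped}")
        elif on_unmapped == "drop":
            warnings.warn(f"dropping unmapped items: {unmapped}", stacklevel=2)
            annual = annual[~annual["item"].isin(unmapped)]
        else:
            raise ValueError("on_unmapped must be 'error' or 'drop'")
    cat = annual["item"].map(factors.categories)
    wide = (
        annual.assign(category=cat)
        .pivot_table(
            index=["household_id", "wave"],
            columns="category",
            values="annual_kg",
            aggfunc="sum",
            fill_value=0.0,
        )
        .reindex(columns=list(CATEGORIES), fill_value=0.0)
    )
    out = wide.add_suffix("_kg")
    out["animal_kg"] = sum(wide[c] for c in ANIMAL_SUBCATEGORIES)
    out["total_kg"] = wide.sum(axis=1)
    total = out["total_kg"].where(out["total_kg"] > 0)
    for c in list(CATEGORIES) + ["animal"]:
        out[f"{c}_pct"] = out[f"{c}_kg"] / total * 100.0
    out["shares_defined"] = out["total_kg"] > 0
    return out.reset_index()


def group_mean_shares(
    cats: pd.DataFrame, convention: str = "ratio_of_means"
) -> pd.Series:
    """Aggregate category shares (%) over household-waves, under either of two
    conventions: ``ratio_of_means`` (mean amounts, then ratio) or
    ``mean_of_shares`` (household-level shares averaged). The two differ in
    general and both are reported; neither is asserted as the study's printed
    convention, which is unstated.
    """
    cols = list(CATEGORIES) + ["animal"]
    if convention == "ratio_of_means":
        mean_kg = cats[[f"{c}_kg" for c in cols]].mean()
        total = cats["total_kg"].mean()
        out = mean_kg / total * 100.0
    elif convention == "mean_of_shares":
        out = cats.loc[cats["shares_defined"], [f"{c}_pct" for c in cols]].mean()
    else:
        raise ValueError("convention must be 'ratio_of_means' or 'mean_of_shares'")
    out.index = [c.removesuffix("_kg").removesuffix("_pct") for c in out.index]
    return out


# ---------------------------------------------------------------------------
# Sample filters
# ---------------------------------------------------------------------------

def winsorize_series(x: pd.Series, limits: float = 0.01) -> pd.Series:
    """Two-sided winsorization by order-statistic clamping.

    The lowest/highest ``floor(n*limits)`` values are replaced by the nearest
    retained order statistic (the scipy.stats.mstats.winsorize convention).
    This is idempotent and, on 100 distinct values 1..100 at 1%, clamps to
    [2, 99].
    """
    vals = mstats.winsorize(x.to_numpy(dtype=float), limits=(limits, limits))
    return pd.Series(np.asarray(vals), index=x.index, name=x.name)


def filter_and_winsorize(
    panel: pd.DataFrame,
    income_col: str = "hhinc",
    ghg_col: str = "ghg",
    limits: float = 0.01,
    enforce_balance: bool = False,
    waves: list | None = None,
    min_rows: int = 100,
) -> pd.DataFrame:
    """Apply the study's sample filters, in the stated order.

    1. Drop rows with income < 0.
    2. Winsorize income and emissions, each at its own [limits, 1-limits]
       order statistics.
    3. Optionally keep only households present in every wave (balanced panel).

    Refuses to winsorize fewer than ``min_rows`` rows — 1% order statistics
    are meaningless on tiny samples.
    """
    for col in (income_col, ghg_col):
        if col not in panel.columns:
            raise ValueError(f"panel lacks required column {col!r}")
    out = panel[panel[income_col] >= 0].copy()
    if len(out) < min_rows:
        raise ValueError(
            f"winsorization refused: only {len(out)} rows (< {min_rows}); "
            "tail percentiles would be unstable"
        )
    out[income_col] = winsorize_series(out[income_col], limits)
    out[ghg_col] = winsorize_series(out[ghg_col], limits)
    if enforce_balance:
        if waves is None:
            waves = sorted(out["wave"].unique())
        counts = out.groupby("household_id")["wave"].nunique()
        keep = counts[counts == len(waves)].index
        out = out[out["household_id"].isin(keep)]
    return out.reset_index(drop=True)
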