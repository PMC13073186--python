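"""Published reference values for the CHNS 2004–2011 dietary-transition study.

These constants are the study's printed summary numbers: median life-cycle
(LCA, cradle-to-retail) emission factors for the major Chinese food items,
group-average per-capita consumption by income group, recommended daily intake
ranges from the Chinese Food Guide Pagoda (2022), and the headline threshold-
regression estimates. They are used (a) to seed default configuration objects,
(b) as cross-table consistency fixtures in the test suite, and (c) to scale the
synthetic data generator. They are inputs, never asserted as outputs of this
package's computations.
"""

from __future__ import annotations

# --- Median LCA emission factors, kg CO2eq per kg of food -------------------
# Only the factors the study prints. Vegetables, fruit and tubers are described
# only as "below 1 kg CO2eq/kg" and are deliberately absent: users must supply
# an explicit placeholder (see accounting.EmissionFactorTable).
PRINTED_FACTORS: dict[str, tuple[str, float]] = {
    # item: (category, factor)
    "beef": ("livestock", 51.7),
    "pork": ("livestock", 9.8),
    "poultry": ("poultry", 7.8),
    "eggs": ("eggs", 4.2),
    "milk": ("dairy", 2.3),
    "wheat": ("cereal", 1.3),
    "rice": ("cereal", 3.1),
}

#: The nine food categories of the consumption taxonomy.
CATEGORIES = (
    "cereal",
    "tuber",
    "vegetables",
    "fruit",
    "livestock",
    "poultry",
    "eggs",
    "aquatic",
    "dairy",
)

#: "Animal food" is the composite of these four subcategories.
ANIMAL_SUBCATEGORIES = ("livestock", "poultry", "eggs", "aquatic")

# --- Group-average annual per-capita consumption (kg/year) ------------------
# By income group (split at the estimated income threshold).
GROUP_CONSUMPTION_KG: dict[str, dict[str, float]] = {
    "high": {
        "overall": 428.2,
        "cereal": 135.4,
        "tuber": 12.7,
        "vegetables": 112.7,
        "fruit": 30.1,
        "animal": 68.2,
        "livestock": 32.0,
        "poultry": 8.6,
        "eggs": 12.5,
        "aquatic": 15.1,
        "dairy": 11.2,
    },
    "low": {
        "overall": 400.1,
        "cereal": 149.2,
        "tuber": 15.1,
        "vegetables": 120.7,
        "fruit": 18.0,
        "animal": 49.7,
        "livestock": 24.4,
        "poultry": 4.4,
        "eggs": 10.3,
        "aquatic": 10.7,
        "dairy": 4.6,
    },
}

#: Printed within-group percentage shares (%); NOT simple amount ratios — the
#: study's weighting is unstated, so these are kept only for reference.
GROUP_SHARES_PCT: dict[str, dict[str, float]] = {
    "high": {"cereal": 33.3, "tuber": 3.0, "vegetables": 26.4, "fruit": 6.1,
             "animal": 15.9, "livestock": 7.5, "poultry": 2.0, "eggs": 3.0,
             "aquatic": 3.4, "dairy": 2.4},
    "low": {"cereal": 38.9, "tuber": 3.7, "vegetables": 30.0, "fruit": 3.8,
            "animal": 12.3, "livestock": 6.1, "poultry": 1.0, "eggs": 2.6,
            "aquatic": 2.5, "dairy": 1.1},
}

# --- Group-average per-capita daily consumption (g/day) ---------------------
GROUP_DAILY_G: dict[str, dict[str, float]] = {
    "high": {"cereal": 371.1, "tuber": 34.9, "vegetables": 308.8,
             "fruit": 82.4, "animal": 186.9, "dairy": 30.7},
    "low": {"cereal": 408.7, "tuber": 41.4, "vegetables": 330.8,
            "fruit": 49.2, "animal": 136.3, "dairy": 12.6},
}

# --- Recommended per-capita daily intake ranges (g/day) ---------------------
# Chinese Food Guide Pagoda (2022), six aggregated categories.
RECOMMENDED_RANGES_G: dict[str, tuple[float, float]] = {
    "cereal": (200.0, 300.0),
    "tuber": (50.0, 100.0),
    "vegetables": (300.0, 500.0),
    "fruit": (200.0, 350.0),
    "animal": (120.0, 200.0),
    "dairy": (300.0, 500.0),
}

# --- Headline threshold-regression estimates --------------------------------
# Income in CPI-adjusted 10,000-yuan units (2015 base); emissions in tons
# CO2eq/year. Used to scale the synthetic data generating process.
HEADLINE = {
    "gamma": 6.5479,
    "gamma_ci": (6.4965, 6.5917),
    "p_single_threshold": 0.035,
    "beta_low": 0.0547,
    "beta_high": 0.0203,
    "adj_r2": 0.243,
    "n_obs": 8288,
    "n_low": 7232,
    "n_high": 1056,
    "controls": {
        "hhsize": 0.935,
        "age06": -0.153,
        "age65": -0.0507,
        "age": -0.00731,
        "edu": 0.0110,
        "marriage": -0.143,
    },
    "const": 0.715,
}
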