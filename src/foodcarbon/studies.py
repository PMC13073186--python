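"""Monte-Carlo studies of the threshold estimator's operating characteristics.

Three repeated-simulation experiments over the synthetic panel generator:

* size of the bootstrap threshold-number test under a no-threshold (equal
  slopes) data generating process,
* recovery of the threshold and regime slopes, and coverage of the LR
  confidence set, under the reference study's slope scale
  (0.0547 / 0.0203 tons per 10,000 yuan, threshold 6.5),
* the footprint round-trip error of the recall-record generator.

Problem sizes default to what each experiment needs statistically (200
size replicates with 99-draw bootstraps; 100 recovery replicates at 1000
households) while staying desk-scale; see docs/methods.md.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .accounting import annualize, footprint
from .reference import HEADLINE
from .synthetic import SyntheticConfig, generate_panel, generate_recall_records, synthetic_factor_table
from .threshold import estimate_threshold, threshold_number_test

__all__ = [
    "size_config",
    "recovery_config",
    "bootstrap_size_study",
    "recovery_study",
    "roundtrip_study",
]


def size_config(seed: int, n_households: int = 200) -> SyntheticConfig:
    """No-threshold DGP: both regimes share the pooled slope, everything else
    at panel defaults."""
    slope = 0.5 * (HEADLINE["beta_low"] + HEADLINE["beta_high"])
    return SyntheticConfig(
        n_households=n_households,
        beta_low=slope,
        beta_high=slope,
        seed=seed,
    )


def recovery_config(
    seed: int, n_households: int = 1000, sigma_eps: float = 0.1
) -> SyntheticConfig:
    """Threshold DGP at the reference slope scale with small noise, for
    parameter-recovery experiments."""
    return SyntheticConfig(
        n_households=n_households,
        true_gamma=6.5,
        beta_low=HEADLINE["beta_low"],
        beta_high=HEADLINE["beta_high"],
        sigma_eps=sigma_eps,
        seed=seed,
    )


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def bootstrap_size_study(
    n_mc: int = 200,
    n_boot: int = 99,
    n_households: int = 200,
    nominal: float = 0.05,
    seed: int = 0,
    max_grid: int | None = None,
) -> dict:
    """Empirical size of the 0-vs-1 threshold bootstrap test.

    Generates ``n_mc`` independent panels under the equal-slopes DGP, runs
    the single-threshold bootstrap test on each, and reports the fraction of
    p-values at or below ``nominal``. For a correctly sized test this
    rejection rate is close to the nominal level.
    """
    seeds = _spawn_seeds(seed, 2 * n_mc).reshape(2, n_mc)
    pvals = np.empty(n_mc)
    for i in range(n_mc):
        cfg = size_config(int(seeds[0, i]), n_households)
        panel = generate_panel(cfg)
        test = threshold_number_test(
            panel,
            n_boot=n_boot,
            max_thresholds=1,
            seed=int(seeds[1, i]),
            max_grid=max_grid,
        )
        pvals[i] = test.p_value(1)
    return {
        "n_mc": n_mc,
        "n_boot": n_boot,
        "n_households": n_households,
        "nominal": nominal,
        "rejection_rate": float(np.mean(pvals <= nominal)),
        "p_values": pvals,
    }


def recovery_study(
    n_mc: int = 100,
    n_households: int = 1000,
    sigma_eps: float = 0.1,
    alpha: float = 0.05,
    seed: int = 0,
    max_grid: int | None = None,
) -> dict:
    """Threshold/slope recovery and LR confidence-set coverage.

    Each replicate draws a fresh panel from the threshold DGP, estimates the
    model, and records the threshold estimate, the LR confidence set at level
    ``alpha``, and both regime slopes. Reports coverage of the true threshold,
    mean relative slope bias, and average interval width.
    """
    seeds = _spawn_seeds(seed, n_mc)
    rows = []
    for i in range(n_mc):
        cfg = recovery_config(int(seeds[i]), n_households, sigma_eps)
        panel = generate_panel(cfg)
        fit = estimate_threshold(panel, alpha=alpha, max_grid=max_grid)
        lo, hi = fit.confidence_set(alpha)
        rows.append(
            {
                "gamma_hat": fit.gamma_hat,
                "ci_low": lo,
                "ci_high": hi,
                "covered": lo <= cfg.true_gamma <= hi,
                "beta_low": fit.beta_low,
                "beta_high": fit.beta_high,
            }
        )
    df = pd.DataFrame(rows)
    cfg0 = recovery_config(0, n_households, sigma_eps)
    return {
        "n_mc": n_mc,
        "n_households": n_households,
        "true_gamma": cfg0.true_gamma,
        "coverage": float(df["covered"].mean()),
        "mean_gamma_hat": float(df["gamma_hat"].mean()),
        "bias_beta_low": float(df["beta_low"].mean() - cfg0.beta_low),
        "bias_beta_high": float(df["beta_high"].mean() - cfg0.beta_high),
        "rel_bias_beta_low": float(
            abs(df["beta_low"].mean() - cfg0.beta_low) / cfg0.beta_low
        ),
        "rel_bias_beta_high": float(
            abs(df["beta_high"].mean() - cfg0.beta_high) / cfg0.beta_high
        ),
        "mean_ci_width": float((df["ci_high"] - df["ci_low"]).mean()),
        "replicates": df,
    }


def roundtrip_study(seed: int = 0, n_households: int = 500) -> dict:
    """Max relative error of footprint(annualize(recall)) vs the panel ghg
    (clipped at zero) on a fresh synthetic draw."""
    cfg = SyntheticConfig(n_households=n_households, seed=seed)
    panel = generate_panel(cfg)
    rec = generate_recall_records(cfg, panel)
    ghg = footprint(annualize(rec), synthetic_factor_table())
    target = (
        panel.set_index(["household_id", "wave"])["ghg"].clip(lower=0.0)
        .reindex(ghg.index)
    )
    denom = np.maximum(np.abs(target.to_numpy()), 1e-300)
    rel = np.abs(ghg.to_numpy() - target.to_numpy()) / denom
    rel = rel[target.to_numpy() > 0]
    return {
        "n_households": n_households,
        "max_rel_error": float(rel.max()),
        "n_rows": int(len(rel)),
    }
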