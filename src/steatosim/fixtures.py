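"""Synthetic observable cohorts for target fitting and sampler tests.

Individual-level (liver fat %, fasting plasma TG) cohort data of the kind the
virtual-population target is meant to be fitted to are rarely redistributable,
so this module generates a *synthetic* stand-in: a positively correlated
joint log-normal spanning healthy through NAFLD-with-hyperlipidemia ranges.
The defaults (median liver fat 4.5 %, median TG 110 mg/dL, log-SDs 0.75 and
0.45, correlation 0.45) put roughly 44 % of the implied population above the
5 % liver-fat NAFLD threshold.  These are documented fixture values, not
clinical data; any user cohort CSV can replace them via
:func:`steatosim.selection.fit_target`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .selection import TargetDistribution

__all__ = [
    "FixtureConfig",
    "DEFAULT_FIXTURE_TARGET",
    "generate_fixture_cohort",
    "write_fixture_cohort",
    "generate_toy_plausible_cloud",
    "TOY_CLOUD_TARGET",
    "cloud_covers_target",
]

#: Fixture joint log-normal over (liver fat %, plasma TG mg/dL).
DEFAULT_FIXTURE_TARGET = TargetDistribution(
    mu=(float(np.log(4.5)), float(np.log(110.0))),
    sigma=(0.75, 0.45),
    rho=0.45,
)

#: Broad cloud emulating the observable scatter of a plausible population,
#: for sampler tests that need no ODE solves.  Wider than the fixture target
#: in both margins so the target's support is covered.
TOY_CLOUD_TARGET = TargetDistribution(
    mu=(float(np.log(4.5)), float(np.log(110.0))),
    sigma=(1.2, 0.8),
    rho=0.2,
)


@dataclass(frozen=True)
class FixtureConfig:
    """Configuration of the synthetic cohort generator."""

    n: int = 1000
    mu: tuple = DEFAULT_FIXTURE_TARGET.mu
    sigma: tuple = DEFAULT_FIXTURE_TARGET.sigma
    rho: float = DEFAULT_FIXTURE_TARGET.rho
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        TargetDistribution(mu=self.mu, sigma=self.sigma, rho=self.rho)  # validates

    @property
    def target(self) -> TargetDistribution:
        return TargetDistribution(mu=self.mu, sigma=self.sigma, rho=self.rho)

    def to_dict(self) -> dict:
        return {"n": self.n, "mu": list(self.mu), "sigma": list(self.sigma),
                "rho": self.rho, "seed": self.seed, "synthetic_fixture": True}


def generate_fixture_cohort(config: FixtureConfig = FixtureConfig()) -> pd.DataFrame:
    """Draw a synthetic (liver fat %, plasma TG) cohort table, reproducibly."""
    rng = np.random.default_rng(config.seed)
    obs = config.target.sample(rng, config.n)
    return pd.DataFrame(obs, columns=["liver_fat_pct", "plasma_tg_mgdl"])


def write_fixture_cohort(config: FixtureConfig, path) -> pd.DataFrame:
    """Write the cohort CSV plus a metadata sidecar flagging it as synthetic."""
    df = generate_fixture_cohort(config)
    path = Path(path)
    df.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(config.to_dict(), indent=2) + "\n")
    return df


def generate_toy_plausible_cloud(
    n: int, seed: int, target: TargetDistribution = TOY_CLOUD_TARGET
) -> pd.DataFrame:
    """Observable-only stand-in for a plausible population (no ODE solves).

    Returns a frame with the plausible-population observable columns
    (``liver_fat_pct``, ``plasma_tg``).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    obs = target.sample(rng, n)
    return pd.DataFrame(obs, columns=["liver_fat_pct", "plasma_tg"])


def cloud_covers_target(
    cloud: pd.DataFrame,
    target: TargetDistribution,
    quantiles=(0.005, 0.995),
    n_grid: int = 9,
) -> bool:
    """Check a cloud covers the target's support in log-observable space.

    Lays a marginal-quantile grid over the target and requires every grid
    point to have at least one cloud point within one Silverman KDE bandwidth
    (per-dimension).
    """
    from scipy.stats import norm

    log_cloud = np.log(cloud.iloc[:, :2].to_numpy(dtype=float))
    n = log_cloud.shape[0]
    bw = log_cloud.std(axis=0, ddof=1) * n ** (-1.0 / 6.0)
    qs = np.linspace(quantiles[0], quantiles[1], n_grid)
    g1 = np.asarray(target.mu)[0] + np.asarray(target.sigma)[0] * norm.ppf(qs)
    g2 = np.asarray(target.mu)[1] + np.asarray(target.sigma)[1] * norm.ppf(qs)
    for x in g1:
        for y in g2:
            d = np.abs(log_cloud - [x, y]) / bw
            if not np.any(np.max(d, axis=1) <= 1.0):
                return False
    return True
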