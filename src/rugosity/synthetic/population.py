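"""Synthetic F2-like fruit population with planted rugosity-texture effects.

Each fruit gets a true rugosity level (1-4), an RI drawn from a truncated
normal confined to that level's interval, an ordinal sensory grade that
equals the true level except for occasional neighbour misgrades, and a panel
of texture / cell-wall / enzyme indicators whose per-level means are
configured directly.  Defaults plant the qualitative pattern reported for
rugose pepper: rupture force, hardness, adhesiveness and chewiness fall with
level (rupture force by a factor 6.55 between levels 1 and 4), shear force is
flat, and beta-galactosidase, polygalacturonase and ionically soluble pectin
rise with level.

Because the per-level RI distributions and the misgrade process are fully
parametric, the population correlation between RI and sensory grade has a
closed form; :func:`calibrate_sensory_misgrade` inverts it so a population
can be tuned to a target sensory-on-RI R-squared (e.g. the 0.659 regime of a
real 277-fruit F2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from ..contour import DEFAULT_LEVEL_SCHEME, LevelScheme
from ..errors import InvalidParameterError

__all__ = [
    "PopulationConfig",
    "INDICATOR_COLUMNS",
    "generate_population",
    "population_sensory_r2",
    "calibrate_sensory_misgrade",
]

#: indicator column order of the phenotype CSV dialect
INDICATOR_COLUMNS = (
    "RF", "HD", "AD", "CH", "SF",
    "WSP", "ISP", "CSP", "CEL", "HEM",
    "bGAL", "PG", "CX", "PME",
)

# per-level means (levels 1..4) and noise SD for each indicator; units follow
# texture-analyzer / biochemical conventions (N, mJ, mg/g, U/g)
_DEFAULT_INDICATORS: Mapping[str, tuple[tuple[float, float, float, float], float]] = {
    "RF": ((65.5, 40.0, 22.0, 10.0), 6.0),   # rupture force: level1/level4 = 6.55
    "HD": ((55.0, 45.0, 36.0, 28.0), 5.0),
    "AD": ((4.0, 3.2, 2.5, 1.8), 0.5),
    "CH": ((30.0, 24.0, 18.0, 12.0), 4.0),
    "SF": ((18.0, 18.0, 18.0, 18.0), 3.0),   # no planted effect
    "WSP": ((1.2, 1.2, 1.2, 1.2), 0.2),
    "ISP": ((0.8, 0.9, 1.0, 1.2), 0.15),
    "CSP": ((1.5, 1.5, 1.5, 1.5), 0.2),
    "CEL": ((12.0, 12.0, 12.0, 12.0), 1.5),
    "HEM": ((8.0, 8.0, 8.0, 8.0), 1.0),
    "bGAL": ((10.0, 13.0, 16.0, 20.0), 2.0),
    "PG": ((5.0, 7.0, 9.0, 12.0), 1.5),
    "CX": ((3.0, 3.0, 3.0, 3.0), 0.5),
    "PME": ((2.0, 2.0, 2.0, 2.0), 0.4),
}


@dataclass(frozen=True)
class PopulationConfig:
    """Parameters of the synthetic fruit population."""

    n_fruits: int = 277
    level_proportions: tuple[float, float, float, float] = (0.2, 0.3, 0.3, 0.2)
    ri_mean_by_level: tuple[float, float, float, float] = (0.8, 2.0, 3.0, 4.5)
    ri_sd_by_level: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.45)
    ri_max_percent: float = 8.0  # right cap of the open level-4 interval
    sensory_misgrade_prob: float = 0.25
    indicator_level_means: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {k: v[0] for k, v in _DEFAULT_INDICATORS.items()}
    )
    indicator_noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {k: v[1] for k, v in _DEFAULT_INDICATORS.items()}
    )
    scheme: LevelScheme = DEFAULT_LEVEL_SCHEME
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fruits < 1:
            raise InvalidParameterError("n_fruits must be positive")
        props = np.asarray(self.level_proportions, float)
        if props.shape != (4,) or np.any(props < 0):
            raise InvalidParameterError("level_proportions must be 4 non-negative reals")
        if abs(props.sum() - 1.0) > 1e-9:
            raise InvalidParameterError("level_proportions must sum to 1 within 1e-9")
        means = np.asarray(self.ri_mean_by_level, float)
        if np.any(np.diff(means) <= 0):
            raise InvalidParameterError("ri_mean_by_level must be strictly increasing")
        lows, highs = self._level_intervals()
        if np.any(means < lows) or np.any(means > highs):
            raise InvalidParameterError("ri_mean_by_level must lie inside the level intervals")
        if np.any(np.asarray(self.ri_sd_by_level, float) < 0):
            raise InvalidParameterError("ri_sd_by_level must be non-negative")
        if not 0.0 <= self.sensory_misgrade_prob <= 1.0:
            raise InvalidParameterError("sensory_misgrade_prob must be in [0, 1]")
        if self.ri_max_percent <= self.scheme.boundaries_percent[-1]:
            raise InvalidParameterError("ri_max_percent must exceed the top level boundary")

    def _level_intervals(self) -> tuple[np.ndarray, np.ndarray]:
        b = self.scheme.boundaries_percent
        lows = np.array([0.0, *b])
        highs = np.array([*b, self.ri_max_percent])
        return lows, highs

    def noise_free(self) -> "PopulationConfig":
        """Copy with all stochastic components switched off (level means only)."""
        return replace(
            self,
            ri_sd_by_level=(0.0, 0.0, 0.0, 0.0),
            sensory_misgrade_prob=0.0,
            indicator_noise_sd={k: 0.0 for k in self.indicator_noise_sd},
        )


def _ri_level_moments(config: PopulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Mean and variance of the truncated-normal RI within each level interval."""
    lows, highs = config._level_intervals()
    means = np.empty(4)
    variances = np.empty(4)
    for i in range(4):
        mu = config.ri_mean_by_level[i]
        sd = config.ri_sd_by_level[i]
        if sd == 0:
            means[i], variances[i] = mu, 0.0
        else:
            a, b = (lows[i] - mu) / sd, (highs[i] - mu) / sd
            m, v = truncnorm.stats(a, b, loc=mu, scale=sd, moments="mv")
            means[i], variances[i] = float(m), float(v)
    return means, variances


def _sensory_conditional_moments(q: float) -> tuple[np.ndarray, np.ndarray]:
    """E[S | level] and E[S^2 | level] under the neighbour-misgrade model."""
    e1 = np.empty(4)
    e2 = np.empty(4)
    for i, lvl in enumerate((1, 2, 3, 4)):
        if lvl == 1:
            grades, probs = (1, 2), (1 - q, q)
        elif lvl == 4:
            grades, probs = (4, 3), (1 - q, q)
        else:
            grades, probs = (lvl, lvl - 1, lvl + 1), (1 - q, q / 2, q / 2)
        g = np.array(grades, float)
        p = np.array(probs, float)
        e1[i] = float(p @ g)
        e2[i] = float(p @ g**2)
    return e1, e2


def population_sensory_r2(config: PopulationConfig) -> float:
    """Closed-form population R-squared of sensory grade regressed on RI.

    Given the level proportions, within-level truncated-normal RI moments and
    the misgrade kernel, RI and sensory grade are conditionally independent
    given the true level, so all moments reduce to sums over levels.
    """
    p = np.asarray(config.level_proportions, float)
    mu, v = _ri_level_moments(config)
    s1, s2 = _sensory_conditional_moments(config.sensory_misgrade_prob)
    e_ri = p @ mu
    var_ri = p @ (v + mu**2) - e_ri**2
    e_s = p @ s1
    var_s = p @ s2 - e_s**2
    if var_ri <= 0 or var_s <= 0:
        raise InvalidParameterError("degenerate population: zero variance in RI or grade")
    cov = p @ (mu * s1) - e_ri * e_s
    return float(cov**2 / (var_ri * var_s))


def calibrate_sensory_misgrade(
    target_r2: float,
    config: PopulationConfig | None = None,
) -> PopulationConfig:
    """Tune the misgrade probability so the population sensory-on-RI R^2 hits a target.

    Uses root finding on the closed-form :func:`population_sensory_r2`, which
    is monotone decreasing in the misgrade probability.
    """
    base = config if config is not None else PopulationConfig()
    lo_r2 = population_sensory_r2(replace(base, sensory_misgrade_prob=0.0))
    hi_r2 = population_sensory_r2(replace(base, sensory_misgrade_prob=0.95))
    if not (hi_r2 <= target_r2 <= lo_r2):
        raise InvalidParameterError(
            f"target R^2 {target_r2} outside attainable range [{hi_r2:.3f}, {lo_r2:.3f}]"
        )
    q = brentq(
        lambda qq: population_sensory_r2(replace(base, sensory_misgrade_prob=qq)) - target_r2,
        0.0,
        0.95,
        xtol=1e-10,
    )
    return replace(base, sensory_misgrade_prob=float(q))


def generate_population(config: PopulationConfig) -> pd.DataFrame:
    """Draw a fruit phenotype table with known ground truth.

    Returns a DataFrame in the phenotype CSV dialect
    (``fruit_id,ri_percent,sensory_level,RF,...,PME``) plus a ``true_level``
    column recording each fruit's generating level.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_fruits
    levels = rng.choice(np.arange(1, 5), size=n, p=np.asarray(config.level_proportions))
    lows, highs = config._level_intervals()

    ri = np.empty(n)
    for i in range(4):
        idx = levels == i + 1
        if not idx.any():
            continue
        mu = config.ri_mean_by_level[i]
        sd = config.ri_sd_by_level[i]
        if sd == 0:
            ri[idx] = mu
        else:
            a, b = (lows[i] - mu) / sd, (highs[i] - mu) / sd
            ri[idx] = truncnorm.rvs(a, b, loc=mu, scale=sd, size=int(idx.sum()), random_state=rng)
    ri = np.maximum(ri, 0.0)  # truncation already enforces this; belt and braces

    sensory = levels.copy()
    mis = rng.random(n) < config.sensory_misgrade_prob
    direction = np.where(rng.random(n) < 0.5, -1, 1)
    neighbour = np.clip(levels + direction, 1, 4)
    # at the edges the only neighbour is inward
    neighbour = np.where(levels == 1, 2, neighbour)
    neighbour = np.where(levels == 4, 3, neighbour)
    sensory = np.where(mis, neighbour, sensory)

    data = {
        "fruit_id": [f"F{i + 1:04d}" for i in range(n)],
        "ri_percent": ri,
        "sensory_level": sensory.astype(int),
    }
    for name in INDICATOR_COLUMNS:
        level_means = np.asarray(config.indicator_level_means[name], float)
        sd = float(config.indicator_noise_sd[name])
        values = level_means[levels - 1]
        if sd > 0:
            values = values + rng.normal(0.0, sd, size=n)
        data[name] = values
    frame = pd.DataFrame(data)
    frame["true_level"] = levels.astype(int)
    return frame
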