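"""Monte-Carlo power of the max-HC detection rule in the rare/weak regime.

A design-stage calculation: of n_features candidate edges, k_nonnull carry a
population correlation ``effect`` with the (standardized) worry score and
the rest are pure noise.  Each simulation draws the worry vector and feature
outcomes, computes per-feature two-sided p-values from the simple-regression
t statistic, and applies the higher-criticism global decision; power is the
rejection fraction.  Covariates are treated as orthogonal noise at design
stage — the full-covariate pipeline lives in the main modules.

With the defaults (22,366 features, 100 non-null, effect 0.1, threshold 2)
this reproduces the design-stage claim that such a signal is detectable with
roughly 81 participants.  Note the threshold-2 full-range rule is
anticonservative under the global null for ensembles this large; the null
rejection rate can be estimated by setting effect = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .hc import hc_curve, hc_decide


@dataclass(frozen=True)
class PowerScenario:
    """One cell of the power simulation grid."""

    n_subjects: int
    n_features: int = 22366
    k_nonnull: int = 100
    effect: float = 0.1         # population worry-feature correlation
    threshold: float = 2.0
    n_sims: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.k_nonnull <= self.n_features:
            raise ValueError("k_nonnull must lie in [0, n_features]")
        if not abs(self.effect) < 1:
            raise ValueError("effect must be a correlation with |effect| < 1")
        if self.n_sims < 1:
            raise ValueError("n_sims must be at least 1")
        if self.n_subjects <= 3:
            raise ValueError("need more than 3 subjects for a t statistic")


@dataclass
class PowerEstimate:
    power: float
    se: float
    scenario: PowerScenario
    n_rejects: int

    def to_dict(self) -> dict:
        d = {"power": self.power, "se": self.se, "n_rejects": self.n_rejects}
        d.update(
            {
                "n_subjects": self.scenario.n_subjects,
                "n_features": self.scenario.n_features,
                "k_nonnull": self.scenario.k_nonnull,
                "effect": self.scenario.effect,
                "threshold": self.scenario.threshold,
                "n_sims": self.scenario.n_sims,
                "seed": self.scenario.seed,
            }
        )
        return d


def _simulate_once(rng: np.random.Generator, sc: PowerScenario) -> bool:
    n, F, k = sc.n_subjects, sc.n_features, sc.k_nonnull
    w = rng.standard_normal(n)
    Y = rng.standard_normal((n, F))
    if k and sc.effect:
        # population corr(w, y) = effect on the first k features
        Y[:, :k] = sc.effect * w[:, None] + math.sqrt(1 - sc.effect**2) * Y[:, :k]
    wc = w - w.mean()
    Yc = Y - Y.mean(axis=0)
    denom = np.sqrt((wc @ wc) * np.einsum("ij,ij->j", Yc, Yc))
    r = (Yc.T @ wc) / denom
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    curve = hc_curve(p)
    return hc_decide(curve, sc.threshold).reject


def simulate_power(scenario: PowerScenario) -> PowerEstimate:
    """Estimate rejection power of the max-HC rule by Monte Carlo.

    Simulation j uses the child RNG seeded from (seed, j), so estimates are
    reproducible and grid points can share random numbers by sharing seeds.
    """
    rejects = 0
    for j in range(scenario.n_sims):
        rng = np.random.default_rng([scenario.seed, j])
        rejects += _simulate_once(rng, scenario)
    power = rejects / scenario.n_sims
    se = math.sqrt(power * (1 - power) / scenario.n_sims)
    return PowerEstimate(power, se, scenario, rejects)


def expected_null_significant(n_features: int, alpha: float) -> tuple[int, float]:
    """Expected count of nominally significant tests under a global null.

    Returns (nearest-integer count, exact expectation alpha * n_features);
    e.g. 22,366 features at alpha = 0.05 give 1118 expected false positives,
    the scale of the multiple-comparisons problem HC addresses.
    """
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    if n_features < 0:
        raise ValueError("n_features must be non-negative")
    exact = alpha * n_features
    return int(round(exact)), exact


@dataclass
class MinimalNResult:
    n_min: int | None           # None when the target is not reached on the grid
    target_power: float
    table: pd.DataFrame         # n, power, se per grid point

    @property
    def reached(self) -> bool:
        return self.n_min is not None


def minimal_n_for_power(
    template: PowerScenario,
    target_power: float = 0.8,
    n_grid: tuple[int, ...] = (41, 61, 81, 101, 121),
) -> MinimalNResult:
    """Smallest grid sample size at which estimated power reaches the target.

    Common random numbers: each simulation draws one worry vector and noise
    matrix at the largest grid n and every smaller n reuses its leading
    rows, so the power-vs-n curve is smooth in n and the grid comparison is
    low-variance.  Returns the full power table either way; ``n_min`` is
    None if no grid point reaches the target.
    """
    if not 0 < target_power < 1:
        raise ValueError("target_power must lie in (0, 1)")
    grid = list(n_grid)
    if grid != sorted(grid) or len(set(grid)) != len(grid):
        raise ValueError("n_grid must be strictly ascending")
    n_max = grid[-1]
    sc = replace(template, n_subjects=n_max)  # validates the largest cell
    F, k = sc.n_features, sc.k_nonnull
    rejects = np.zeros(len(grid), dtype=np.int64)
    for j in range(sc.n_sims):
        rng = np.random.default_rng([sc.seed, j])
        w_full = rng.standard_normal(n_max)
        E_full = rng.standard_normal((n_max, F))
        for g, n in enumerate(grid):
            if n <= 3:
                raise ValueError("every grid n must exceed 3")
            w = w_full[:n]
            Y = E_full[:n].copy()
            if k and sc.effect:
                Y[:, :k] = sc.effect * w[:, None] + math.sqrt(1 - sc.effect**2) * Y[:, :k]
            wc = w - w.mean()
            Yc = Y - Y.mean(axis=0)
            denom = np.sqrt((wc @ wc) * np.einsum("ij,ij->j", Yc, Yc))
            r = np.clip((Yc.T @ wc) / denom, -1 + 1e-15, 1 - 1e-15)
            t = r * np.sqrt((n - 2) / (1.0 - r**2))
            p = 2.0 * stats.t.sf(np.abs(t), n - 2)
            rejects[g] += hc_decide(hc_curve(p), sc.threshold).reject
    power = rejects / sc.n_sims
    se = np.sqrt(power * (1 - power) / sc.n_sims)
    table = pd.DataFrame({"n": grid, "power": power, "se": se})
    reached = np.flatnonzero(power >= target_power)
    n_min = int(grid[reached[0]]) if reached.size else None
    return MinimalNResult(n_min, target_power, table)
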