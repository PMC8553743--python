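"""Higher criticism: second-level testing of a p-value ensemble.

Given n per-edge p-values, arrange them in ascending order p_(1) <= ... <=
p_(n) and compare each to its expectation under the global null (uniform
p-values)::

    HC_i = sqrt(n) * (i/n - p_(i)) / sqrt((i/n) * (1 - i/n))

Each HC_i is a z-like score (binomial mean i/n, variance i/n(1-i/n)/n), so
for large n a maximum above ~2 signals a significant deviation from
uniformity — evidence of a rare/weak signal even when no single test would
survive multiple-testing correction.  The rank at which the HC curve peaks
(i*) doubles as a selection cutoff: the i* smallest p-values are the tests
contributing the most evidence against the global null.  Selection carries
no per-edge type-I error control; it is an evidence ranking, not an FDR/FWER
procedure.

The statistic is evaluated at ranks 1..n-1 (the variance vanishes at i = n).
Optional restrictions — ``alpha0`` (only ranks with i/n <= alpha0) and
``plus`` (ignore ranks with p_(i) < 1/n) — implement the standard stabilized
variants and are off by default.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300


@dataclass
class HCCurve:
    """HC trajectory over sorted p-values."""

    n_tests: int
    sorted_p: np.ndarray
    order: np.ndarray          # rank i (0-based) -> original index / edge id
    hc: np.ndarray             # HC_i for i = 1..n-1
    eval_mask: np.ndarray      # ranks actually eligible for the maximum
    hc_max: float
    i_star: int                # 1-based rank of the maximum

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, self.n_tests, dtype=np.int64),
                "p": self.sorted_p[:-1],
                "hc": self.hc,
                "edge_id": self.order[:-1],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def hc_curve(p_values, alpha0: float | None = None, plus: bool = False) -> HCCurve:
    """Compute the HC trajectory of a p-value ensemble.

    Uses a stable sort (ties keep input order); exact zeros are floored at
    1e-300 with a warning so upstream underflow stays visible.  Tied maxima
    resolve to the smallest rank.
    """
    p = np.asarray(p_values, dtype=float).copy()
    if p.ndim != 1 or p.size < 2:
        raise ValueError("need a 1-D vector of at least 2 p-values")
    if np.any(np.isnan(p)):
        raise ValueError("NaN p-value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    n_zero = int(np.sum(p == 0))
    if n_zero:
        logger.warning("flooring %d zero p-value(s) at %g", n_zero, P_FLOOR)
        p[p == 0] = P_FLOOR
    n = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    i = np.arange(1, n)              # evaluate at ranks 1..n-1
    u = i / n
    hc = np.sqrt(n) * (u - sorted_p[:-1]) / np.sqrt(u * (1.0 - u))
    mask = np.ones(n - 1, dtype=bool)
    if alpha0 is not None:
        if not 0 < alpha0 <= 1:
            raise ValueError("alpha0 must lie in (0, 1]")
        mask &= u <= alpha0
    if plus:
        mask &= sorted_p[:-1] >= 1.0 / n
    if not mask.any():
        raise ValueError("no ranks remain after alpha0/plus restrictions")
    masked = np.where(mask, hc, -np.inf)
    hc_max = float(masked.max())
    i_star = int(np.flatnonzero(masked == hc_max)[0]) + 1
    return HCCurve(n, sorted_p, order.astype(np.int64), hc, mask, hc_max, i_star)


@dataclass
class GlobalDecision:
    """Global rare/weak detection decision: reject iff hc_max > threshold."""

    hc_max: float
    threshold: float
    reject: bool
    i_star: int
    n_tests: int

    def to_dict(self) -> dict:
        return {
            "hc_max": self.hc_max,
            "threshold": self.threshold,
            "reject": self.reject,
            "i_star": self.i_star,
            "n_tests": self.n_tests,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def hc_decide(curve: HCCurve, threshold: float = 2.0) -> GlobalDecision:
    """Reject the global null iff the maximum HC statistic exceeds ``threshold``.

    The default 2 reads each HC_i as an approximate standard-normal score;
    because the decision takes a maximum over many correlated ranks, the rule
    is anticonservative under the null for large ensembles (its empirical
    null rejection rate is reported by the simulation utilities rather than
    assumed to be 5%).
    """
    return GlobalDecision(
        hc_max=curve.hc_max,
        threshold=float(threshold),
        reject=bool(curve.hc_max > threshold),
        i_star=curve.i_star,
        n_tests=curve.n_tests,
    )


@dataclass
class SelectedSet:
    """Edges whose p-value rank is <= i*: the max-HC selected set."""

    edge_ids: np.ndarray
    p: np.ndarray
    beta: np.ndarray
    beta_std: np.ndarray
    sign: np.ndarray
    i_star: int

    def __len__(self) -> int:
        return self.edge_ids.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "edge_id": self.edge_ids,
                "p": self.p,
                "beta": self.beta,
                "beta_std": self.beta_std,
                "sign": self.sign,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def hc_select(curve: HCCurve, results) -> SelectedSet:
    """Map the i* smallest p-values back to edges, with signs and effects.

    ``results`` is the EdgeRegressionResults whose p-values built the curve.
    """
    if results.n_edges != curve.n_tests:
        raise ValueError("results length does not match the HC curve")
    from .regression import standardized_beta

    ranks = curve.order[: curve.i_star]
    beta_std = standardized_beta(results)
    return SelectedSet(
        edge_ids=ranks.copy(),
        p=results.p[ranks],
        beta=results.beta[ranks],
        beta_std=beta_std[ranks],
        sign=np.sign(results.beta[ranks]).astype(int),
        i_star=curve.i_star,
    )
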