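"""Bootstrap prevalence ranking of HC-selected edges.

Subjects are resampled with replacement; for each resample the design is
rebuilt (categorical levels can collapse under resampling, so encodings are
re-derived; degenerate resamples are redrawn and counted), every edge is
refit, and higher criticism is applied.  If the maximum HC statistic is
below the tally threshold nothing is tallied for that iteration; otherwise
every edge in the max-HC selected set gets a tally.  The resulting
per-edge prevalence ranks edges by the stability of their selection — it is
explicitly NOT a significance test (weak effects are not expected to appear
in 95% of iterations).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hc import hc_curve, hc_select
from .regression import build_design_matrix, fit_edge_regressions

logger = logging.getLogger(__name__)


@dataclass
class TallyTable:
    """Per-edge selection counts over bootstrap iterations."""

    tally: np.ndarray          # integer counts per edge
    B: int                     # iterations requested
    B_informative: int         # iterations with max HC >= threshold
    threshold: float
    seed: int
    redraws: int               # degenerate resamples that were redrawn
    is_significance_test: bool = False  # prevalence ranks importance only

    @property
    def prevalence(self) -> np.ndarray:
        return self.tally / self.B if self.B else np.zeros_like(self.tally, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "edge_id": np.arange(self.tally.size, dtype=np.int64),
                "tally": self.tally,
                "prevalence": self.prevalence,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def manifest(self) -> dict:
        return {
            "B": self.B,
            "B_informative": self.B_informative,
            "threshold": self.threshold,
            "seed": self.seed,
            "redraws": self.redraws,
            "is_significance_test": self.is_significance_test,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=1)


def bootstrap_tally(
    subjects: pd.DataFrame,
    panel,
    B: int = 1000,
    threshold: float = 2.0,
    seed: int = 0,
    madrs_threshold: int = 14,
    hc_kwargs: dict | None = None,
) -> TallyTable:
    """Tally HC-selected edges across ``B`` subject resamples.

    Tallying uses max HC >= threshold (the complement of "less than the
    threshold, tally nothing"), which differs from the strict > of the
    full-sample global decision; both are configurable.  Each iteration uses
    an independent child RNG seeded from (seed, iteration), so results are
    reproducible and order-independent.
    """
    if B < 0:
        raise ValueError("B must be non-negative")
    Y = panel.values if hasattr(panel, "values") else np.asarray(panel, dtype=float)
    n = len(subjects)
    if Y.shape[0] != n:
        raise ValueError("panel rows do not align with the subject table")
    hc_kwargs = hc_kwargs or {}
    tally = np.zeros(Y.shape[1], dtype=np.int64)
    B_informative = 0
    redraws = 0
    max_redraws = max(10, B // 2)
    for b in range(B):
        rng = np.random.default_rng([seed, b])
        while True:
            idx = rng.integers(0, n, size=n)
            boot = subjects.iloc[idx].reset_index(drop=True)
            try:
                design = build_design_matrix(boot, madrs_threshold=madrs_threshold)
                break
            except ValueError:
                redraws += 1
                if redraws > max_redraws:
                    raise RuntimeError(
                        f"aborting: {redraws} degenerate resamples "
                        "(design cannot survive resampling)"
                    )
        results = fit_edge_regressions(Y[idx], design)
        curve = hc_curve(results.p, **hc_kwargs)
        if curve.hc_max >= threshold:
            B_informative += 1
            selected = hc_select(curve, results)
            tally[selected.edge_ids] += 1
    if redraws:
        logger.info("bootstrap_tally: redrew %d degenerate resample(s)", redraws)
    return TallyTable(tally, B, B_informative, float(threshold), int(seed), redraws)


def rank_edges(tally: TallyTable, results) -> pd.DataFrame:
    """Edges ordered by bootstrap prevalence.

    Descending tally, ties broken by ascending full-sample p, then by edge
    id.  The ranking is a stability/importance ordering, not a significance
    statement.
    """
    if tally.tally.size != results.n_edges:
        raise ValueError("tally and results refer to different edge sets")
    from .regression import standardized_beta

    df = pd.DataFrame(
        {
            "edge_id": np.arange(results.n_edges, dtype=np.int64),
            "tally": tally.tally,
            "prevalence": tally.prevalence,
            "p": results.p,
            "beta": results.beta,
            "beta_std": standardized_beta(results),
        }
    )
    df = df.sort_values(
        ["tally", "p", "edge_id"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)
    return df
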