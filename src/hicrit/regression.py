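"""Mass-univariate edge-wise regression of Fisher-Z connectivity on worry.

Each of the E edges gets the same linear model: Fisher-Z connectivity
regressed on the PSWQ worry score adjusted for age, sex, race, education,
medical burden (CIRS-G), depression (MADRS, dichotomized at 14 because its
distribution is highly skewed), anxiety (HARS), perceived stress (PSS),
rumination (RSQ) and neuroticism (NEO-FFI).  Because the design matrix is
shared, all E ordinary-least-squares fits reduce to one QR factorization and
two matrix products; p-values are two-sided from the t distribution with
n - k residual degrees of freedom (with the default covariate set k = 13, so
n = 77 gives df = 64, where t and z are indistinguishable in practice).

No multiple-testing correction happens here: the higher-criticism module is
the second-level test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

COVARIATE_ORDER = [
    "pswq", "age", "sex", "race", "education", "cirs_g",
    "madrs", "hars", "pss", "rsq", "neo_ffi",
]


def dichotomize_madrs(score, threshold: int = 14):
    """Map MADRS depression scores to {'low', 'high'}; high iff score >= threshold."""
    arr = np.asarray(score)
    if np.any(arr < 0):
        raise ValueError("MADRS scores must be non-negative")
    out = np.where(arr >= threshold, "high", "low")
    return out if arr.ndim else str(out)


@dataclass
class DesignMatrix:
    """Shared n x k design with the worry column flagged.

    Treatment coding with the modal level as reference for each categorical;
    column order is deterministic (intercept, pswq, age, sex dummy, race
    dummies, education, cirs_g, madrs_high, hars, pss, rsq, neo_ffi).
    """

    X: np.ndarray
    columns: list[str]
    worry_index: int
    references: dict[str, str]
    subject_ids: list[str]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def k(self) -> int:
        return self.X.shape[1]

    @property
    def df_resid(self) -> int:
        return self.n - self.k


def _dummies(col: pd.Series, name: str, allow_degenerate: bool):
    levels = col.value_counts()
    if len(levels) == 1:
        if allow_degenerate:
            logger.warning("dropping constant categorical %r (single level %r)",
                           name, levels.index[0])
            return [], [], str(levels.index[0])
        raise ValueError(
            f"categorical {name!r} has a single level {levels.index[0]!r}; "
            "pass allow_degenerate=True to drop it"
        )
    ref = str(levels.index[0])  # modal level as reference
    others = sorted(str(l) for l in levels.index if str(l) != ref)
    cols = [(col.astype(str) == lev).to_numpy(float) for lev in others]
    names = [f"{name}_{lev}" for lev in others]
    return cols, names, ref


def build_design_matrix(
    subjects: pd.DataFrame,
    madrs_threshold: int = 14,
    allow_degenerate: bool = False,
) -> DesignMatrix:
    """Build the worry + 10-confound design from a complete-case subject table."""
    if subjects[[c for c in COVARIATE_ORDER if c in subjects]].isna().any().any():
        raise ValueError("subject table has missing values (complete-case required)")
    n = len(subjects)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    references: dict[str, str] = {}

    def add_numeric(name):
        cols.append(subjects[name].to_numpy(float))
        names.append(name)

    add_numeric("pswq")
    add_numeric("age")
    for cat in ("sex", "race"):
        c, cn, ref = _dummies(subjects[cat], cat, allow_degenerate)
        cols.extend(c)
        names.extend(cn)
        references[cat] = ref
    add_numeric("education")
    add_numeric("cirs_g")
    madrs_cat = pd.Series(dichotomize_madrs(subjects["madrs"].to_numpy(), madrs_threshold))
    if madrs_cat.nunique() == 1:
        if allow_degenerate:
            logger.warning("dropping constant MADRS category")
            references["madrs"] = str(madrs_cat.iloc[0])
        else:
            raise ValueError(
                "madrs category is constant at this threshold; "
                "pass allow_degenerate=True to drop it"
            )
    else:
        cols.append((madrs_cat == "high").to_numpy(float))
        names.append("madrs_high")
        references["madrs"] = "low"
    for name in ("hars", "pss", "rsq", "neo_ffi"):
        add_numeric(name)

    X = np.column_stack(cols)
    k = X.shape[1]
    if n <= k:
        raise ValueError(f"insufficient degrees of freedom: n={n} <= k={k}")
    # name the culprit for obvious degeneracies before the generic rank check
    for j, name in enumerate(names):
        if name != "intercept" and np.ptp(X[:, j]) == 0:
            raise ValueError(f"design column {name!r} is constant")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("design matrix is rank deficient (collinear covariates)")
    return DesignMatrix(
        X, names, names.index("pswq"), references,
        subjects["subject_id"].astype(str).tolist(),
    )


@dataclass
class EdgeRegressionResults:
    """Per-edge worry coefficient, SE, t and two-sided p, in edge-id order."""

    beta: np.ndarray      # Fisher-Z units per PSWQ point
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df: int
    sd_pswq: float
    n: int
    k: int

    @property
    def n_edges(self) -> int:
        return self.beta.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "edge_id": np.arange(self.n_edges, dtype=np.int64),
                "beta": self.beta,
                "se": self.se,
                "t": self.t,
                "p": self.p,
                "beta_std": standardized_beta(self),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def manifest(self) -> dict:
        return {"n": self.n, "k": self.k, "df": self.df,
                "sd_pswq": self.sd_pswq, "n_edges": self.n_edges}


def fit_edge_regressions(panel, design: DesignMatrix) -> EdgeRegressionResults:
    """OLS of every edge on the shared design, vectorized across edges.

    ``panel`` may be a ConnectivityPanel or a plain n x E array aligned with
    the design rows.
    """
    Y = panel.values if hasattr(panel, "values") else np.asarray(panel, dtype=float)
    if hasattr(panel, "subject_ids") and panel.subject_ids != design.subject_ids:
        raise ValueError("panel subject ids do not align with the design")
    if Y.ndim != 2 or Y.shape[0] != design.n:
        raise ValueError("panel rows do not match design rows")
    if not np.all(np.isfinite(Y)):
        raise ValueError("panel contains non-finite values")
    X = design.X
    n, k = X.shape
    df = n - k
    if df < 1:
        raise ValueError("need at least 1 residual degree of freedom")
    Q, R = np.linalg.qr(X)
    coef = np.linalg.solve(R, Q.T @ Y)          # k x E
    resid = Y - X @ coef
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / df
    Rinv = np.linalg.inv(R)
    xtx_inv_diag = np.einsum("ij,ij->i", Rinv, Rinv)
    w = design.worry_index
    beta = coef[w]
    se = np.sqrt(sigma2 * xtx_inv_diag[w])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    sd_pswq = float(X[:, w].std(ddof=1))
    return EdgeRegressionResults(beta, se, t, p, df, sd_pswq, n, k)


def standardized_beta(results: EdgeRegressionResults, full: bool = False,
                      sd_outcome: np.ndarray | None = None) -> np.ndarray:
    """Worry coefficient per 1 SD of PSWQ: beta * sd(PSWQ).

    With ``full=True`` the outcome scale is removed as well
    (beta * sd(PSWQ) / sd(edge)), which requires ``sd_outcome``.
    """
    if results.sd_pswq <= 0:
        raise ValueError("worry score has zero variance")
    b = results.beta * results.sd_pswq
    if full:
        if sd_outcome is None:
            raise ValueError("full standardization needs per-edge outcome SDs")
        b = b / np.asarray(sd_outcome, dtype=float)
    return b
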