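"""Synthetic cohort, connectome annotation and connectivity generators.

Emulates a cross-sectional late-life worry cohort: a subject table carrying
the Penn State Worry Questionnaire (PSWQ) score plus the ten demographic and
clinical confounds used in the edge-wise regressions, a 212-node annotation
spanning the default mode (DMN), anterior salience (ASN) and left executive
control (LECN) networks, and subjects x edges Fisher-Z connectivity panels
with a sparse planted worry signal.  Panels can be generated directly on the
Fisher-Z scale or materialized as band-limited ROI time series with the
matching population correlation structure.

Marginal distributions follow the study cohort: bounded scores are drawn
from moment-matched truncated normals (the latent mean/SD are solved so the
post-truncation moments equal the configured values) and nonnegative skewed
scores (MADRS, HARS, CIRS-G) from moment-matched gammas.  Covariates are
independent by default; an optional Gaussian-copula correlation block can be
requested for the psychometric scales.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .connectome import ConnectivityPanel, EdgeIndex

SUBJECT_COLUMNS = [
    "subject_id", "age", "sex", "race", "education", "cirs_g",
    "madrs", "hars", "pswq", "pss", "rsq", "neo_ffi",
]

NODE_COLUMNS = ["node_id", "label", "network", "region_group", "hemisphere"]

NETWORKS = ("DMN", "ASN", "LECN")

REGION_GROUPS = (
    "default mode", "limbic", "parietal", "prefrontal",
    "sensorimotor", "subcortical", "temporal", "visual",
)

# Cohort marginals (mean/SD per instrument, counts-based category frequencies).
# PSS is on the 10-item 0-40 scale with typical community older-adult values.
DEFAULT_COHORT_CONFIG: dict = {
    "age": {"dist": "truncnorm", "mean": 61.8, "sd": 8.2, "lo": 50.0, "hi": 95.0, "decimals": 1},
    "education": {"dist": "truncnorm", "mean": 16.0, "sd": 2.3, "lo": 8.0, "hi": 24.0, "decimals": 0},
    "cirs_g": {"dist": "gamma", "mean": 3.7, "sd": 3.5, "hi": 56.0, "decimals": 0},
    "madrs": {"dist": "gamma", "mean": 7.4, "sd": 7.9, "hi": 60.0, "decimals": 0},
    "hars": {"dist": "gamma", "mean": 7.4, "sd": 5.7, "hi": 56.0, "decimals": 0},
    "pswq": {"dist": "truncnorm", "mean": 48.2, "sd": 14.6, "lo": 16.0, "hi": 80.0, "decimals": 0},
    "pss": {"dist": "truncnorm", "mean": 13.0, "sd": 7.0, "lo": 0.0, "hi": 40.0, "decimals": 0},
    "rsq": {"dist": "truncnorm", "mean": 37.0, "sd": 12.9, "lo": 22.0, "hi": 88.0, "decimals": 0},
    "neo_ffi": {"dist": "truncnorm", "mean": 19.2, "sd": 9.9, "lo": 0.0, "hi": 48.0, "decimals": 0},
    "sex": {"dist": "categorical", "levels": ["F", "M"], "p": [0.62, 0.38]},
    "race": {"dist": "categorical", "levels": ["W", "B", "MR"], "p": [68 / 77, 8 / 77, 1 / 77]},
}

DEFAULT_ANNOTATION_CONFIG: dict = {
    "networks": {"DMN": 79, "ASN": 78, "LECN": 55},
    "region_groups": {
        "prefrontal": 0.22, "default mode": 0.15, "temporal": 0.15,
        "parietal": 0.12, "limbic": 0.12, "subcortical": 0.08,
        "sensorimotor": 0.08, "visual": 0.08,
    },
    "hemisphere_p": {"L": 0.48, "R": 0.48, "bilateral": 0.04},
}


@lru_cache(maxsize=None)
def _matched_truncnorm(mean: float, sd: float, lo: float, hi: float):
    """Truncated normal on [lo, hi] whose mean/SD equal the targets exactly.

    Solves for the latent (mu, sigma); without this, clipping a normal at the
    instrument bounds would bias the realized moments away from Table-style
    configured values.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    if not lo < hi:
        raise ValueError("need lo < hi")

    def residual(params):
        mu, log_sigma = params
        sigma = math.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [float(m) - mean, math.sqrt(float(v)) - sd]

    sol = optimize.fsolve(residual, [mean, math.log(sd)], xtol=1e-12)
    mu, sigma = float(sol[0]), math.exp(float(sol[1]))
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return stats.truncnorm(a, b, loc=mu, scale=sigma)


def _marginal(spec: Mapping):
    """Frozen scipy distribution implementing one covariate's marginal."""
    kind = spec["dist"]
    if kind == "truncnorm":
        return _matched_truncnorm(spec["mean"], spec["sd"], spec["lo"], spec["hi"])
    if kind == "gamma":
        mean, sd = spec["mean"], spec["sd"]
        if sd <= 0 or mean <= 0:
            raise ValueError("gamma marginal needs positive mean and sd")
        shape = (mean / sd) ** 2
        scale = sd**2 / mean
        return stats.gamma(shape, scale=scale)
    raise ValueError(f"unknown distribution kind {kind!r}")


def _validate_categorical(spec: Mapping, name: str) -> None:
    p = np.asarray(spec["p"], dtype=float)
    if len(p) != len(spec["levels"]):
        raise ValueError(f"{name}: probabilities do not match levels")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
        raise ValueError(f"{name}: probabilities must be non-negative and sum to 1")


def simulate_subjects(n: int, seed: int, config: Mapping | None = None) -> pd.DataFrame:
    """Draw a complete-case synthetic subject table.

    Parameters
    ----------
    n : number of subjects (n=0 yields an empty table with the full header).
    seed : RNG seed; identical (n, seed, config) reproduce identical tables.
    config : per-covariate marginal overrides merged onto the defaults.  The
        optional key ``"psychometric_corr"`` = ``{"vars": [...], "matrix":
        [[...]]}`` imposes a Gaussian-copula correlation among the named
        continuous scales.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    cfg = {k: dict(v) for k, v in DEFAULT_COHORT_CONFIG.items()}
    corr_block = None
    if config:
        for key, val in config.items():
            if key == "psychometric_corr":
                corr_block = val
                continue
            if key not in cfg:
                raise ValueError(f"unknown covariate {key!r}")
            cfg[key].update(val)
    for name, spec in cfg.items():
        if spec["dist"] == "categorical":
            _validate_categorical(spec, name)
        elif spec.get("sd", 1.0) < 0:
            raise ValueError(f"{name}: sd must be non-negative")

    rng = np.random.default_rng(seed)
    continuous = [c for c in SUBJECT_COLUMNS[1:] if cfg[c]["dist"] != "categorical"]
    categorical = [c for c in SUBJECT_COLUMNS[1:] if cfg[c]["dist"] == "categorical"]

    # uniforms first (optionally copula-correlated), then marginal quantiles
    u = {c: rng.uniform(size=n) for c in continuous + categorical}
    if corr_block is not None:
        vars_ = list(corr_block["vars"])
        mat = np.asarray(corr_block["matrix"], dtype=float)
        if mat.shape != (len(vars_), len(vars_)):
            raise ValueError("psychometric_corr matrix shape does not match vars")
        for v in vars_:
            if v not in continuous:
                raise ValueError(f"psychometric_corr var {v!r} is not a continuous covariate")
        L = np.linalg.cholesky(mat)
        z = rng.standard_normal((n, len(vars_))) @ L.T
        for k, v in enumerate(vars_):
            u[v] = stats.norm.cdf(z[:, k])

    data: dict = {"subject_id": [f"S{i:04d}" for i in range(n)]}
    for c in SUBJECT_COLUMNS[1:]:
        spec = cfg[c]
        if spec["dist"] == "categorical":
            cum = np.cumsum(spec["p"])
            idx = np.searchsorted(cum, u[c], side="right").clip(0, len(spec["levels"]) - 1)
            data[c] = np.asarray(spec["levels"], dtype=object)[idx]
        else:
            x = _marginal(spec).ppf(u[c])
            if "hi" in spec:
                x = np.minimum(x, spec["hi"])
            if "lo" in spec:
                x = np.maximum(x, spec["lo"])
            dec = spec.get("decimals")
            if dec is not None:
                x = np.round(x, dec)
                if dec == 0:
                    x = x.astype(int) if c in ("madrs", "hars") else x
            data[c] = x
    df = pd.DataFrame(data, columns=SUBJECT_COLUMNS)
    df["madrs"] = df["madrs"].astype(int)
    df["hars"] = df["hars"].astype(int)
    return df


def make_node_annotation(config: Mapping | None = None, seed: int = 0) -> pd.DataFrame:
    """Deterministic node -> network / region-group annotation table.

    Defaults produce the 212-node connectome (79 DMN, 78 ASN, 55 LECN) with
    region groups assigned by configured proportions over the eight standard
    anatomical groups; the assignment rule is a fixed seeded draw, not
    anatomy (synthetic nodes have no geometry).
    """
    cfg = {k: dict(v) for k, v in DEFAULT_ANNOTATION_CONFIG.items()}
    if config:
        for key, val in config.items():
            if key not in cfg:
                raise ValueError(f"unknown annotation config key {key!r}")
            cfg[key] = dict(val)
    networks = cfg["networks"]
    for name, count in networks.items():
        if name not in NETWORKS:
            raise ValueError(f"unknown network name {name!r}")
        if count < 1:
            raise ValueError(f"network {name!r} needs at least one node")
    groups = list(cfg["region_groups"])
    for g in groups:
        if g not in REGION_GROUPS:
            raise ValueError(f"unknown region group {g!r}")
    gp = np.asarray([cfg["region_groups"][g] for g in groups], dtype=float)
    gp = gp / gp.sum()
    hemis = list(cfg["hemisphere_p"])
    hp = np.asarray([cfg["hemisphere_p"][h] for h in hemis], dtype=float)
    hp = hp / hp.sum()

    rng = np.random.default_rng(seed)
    rows = []
    node_id = 0
    for net in NETWORKS:
        if net not in networks:
            continue
        for k in range(networks[net]):
            group = groups[rng.choice(len(groups), p=gp)]
            hemi = hemis[rng.choice(len(hemis), p=hp)]
            rows.append((node_id, f"{net}_{k:03d}", net, group, hemi))
            node_id += 1
    if not rows:
        raise ValueError("annotation has zero nodes")
    return pd.DataFrame(rows, columns=NODE_COLUMNS)


@dataclass(frozen=True)
class EffectSpec:
    """Planted worry signal for the connectivity generators.

    ``planted`` maps edge ids to slopes in Fisher-Z units per 1 SD of PSWQ
    (worry enters standardized, so these are per-SD effects).  Covariate
    effects, if any, are slopes per 1 SD of the named continuous covariate,
    applied to all edges.  ``noise_sd`` is the across-subject residual SD of
    an edge on the Fisher-Z scale.
    """

    planted: Mapping[int, float] = field(default_factory=dict)
    baseline_z: float | np.ndarray = 0.25
    covariate_effects: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 0.3

    def beta_vector(self, n_edges: int) -> np.ndarray:
        beta = np.zeros(n_edges)
        for e, b in self.planted.items():
            if not 0 <= e < n_edges:
                raise ValueError(f"planted edge id {e} out of range for {n_edges} edges")
            beta[e] = b
        return beta


def plant_random_edges(
    n_edges: int, k: int, beta_per_sd: float, seed: int,
    frac_negative: float = 0.0, **kwargs
) -> EffectSpec:
    """EffectSpec with ``k`` random edges carrying a |slope| of ``beta_per_sd``.

    A fraction ``frac_negative`` of the planted edges (rounded) gets the
    negative sign, mimicking a mix of worry-increasing and worry-decreasing
    connectivities.
    """
    if not 0 <= k <= n_edges:
        raise ValueError("k must lie in [0, n_edges]")
    if not 0 <= frac_negative <= 1:
        raise ValueError("frac_negative must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ids = rng.choice(n_edges, size=k, replace=False)
    n_neg = round(k * frac_negative)
    signs = np.ones(k)
    signs[:n_neg] = -1.0
    rng.shuffle(signs)
    return EffectSpec(
        planted={int(e): s * beta_per_sd for e, s in zip(ids, signs)}, **kwargs
    )


def _standardize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return np.zeros_like(x)
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _subject_mean_z(subjects: pd.DataFrame, effects: EffectSpec, n_edges: int) -> np.ndarray:
    """Noise-free subjects x edges mean Fisher-Z surface."""
    n = len(subjects)
    beta = effects.beta_vector(n_edges)
    base = np.broadcast_to(np.asarray(effects.baseline_z, dtype=float), (n_edges,))
    z = np.tile(base, (n, 1)).astype(float)
    z += np.outer(_standardize(subjects["pswq"].to_numpy()), beta)
    for cov, slope in effects.covariate_effects.items():
        col = subjects[cov]
        if not pd.api.types.is_numeric_dtype(col):
            raise ValueError(f"covariate effect on non-numeric column {cov!r}")
        z += slope * _standardize(col.to_numpy())[:, None]
    return z


def simulate_connectomes(
    subjects: pd.DataFrame,
    annotation: pd.DataFrame,
    effects: EffectSpec,
    seed: int,
) -> ConnectivityPanel:
    """Generate Fisher-Z edge panels directly on the regression scale.

    For subject s and edge e::

        z[s, e] = baseline_z[e] + beta[e] * (pswq_s - mean)/sd
                  + covariate terms + Normal(0, noise_sd)

    with beta zero off the planted set.
    """
    if effects.noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    index = EdgeIndex(len(annotation))
    z = _subject_mean_z(subjects, effects, index.n_edges)
    if effects.noise_sd > 0:
        rng = np.random.default_rng(seed)
        z += rng.normal(0.0, effects.noise_sd, size=z.shape)
    return ConnectivityPanel(z, subjects["subject_id"].astype(str).tolist(), index)


@dataclass
class TimeseriesPanel:
    """Per-subject T x m ROI series with acquisition metadata."""

    series: np.ndarray  # (n_subjects, T, m)
    tr: float
    band: tuple[float, float] | None
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 3:
            raise ValueError("series must be (n_subjects, T, m)")
        if self.series.shape[0] != len(self.subject_ids):
            raise ValueError("subject ids do not match series")

    @property
    def T(self) -> int:
        return self.series.shape[1]

    @property
    def m(self) -> int:
        return self.series.shape[2]

    def to_dir(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        files = {}
        for s, sid in enumerate(self.subject_ids):
            fname = f"{sid}.tsv"
            np.savetxt(out / fname, self.series[s], delimiter="\t", fmt="%.8g")
            files[sid] = fname
        manifest = {
            "tr": self.tr,
            "band": list(self.band) if self.band else None,
            "T": self.T,
            "m": self.m,
            "subjects": files,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def from_dir(cls, in_dir) -> "TimeseriesPanel":
        root = Path(in_dir)
        manifest = json.loads((root / "manifest.json").read_text())
        sids = list(manifest["subjects"])
        series = np.stack(
            [np.loadtxt(root / manifest["subjects"][sid], delimiter="\t") for sid in sids]
        )
        band = manifest["band"]
        return cls(series, manifest["tr"], tuple(band) if band else None, sids)


def nearest_correlation(mat: np.ndarray, eig_floor: float = 1e-8) -> np.ndarray:
    """Nearest-positive-definite repair by eigenvalue clipping + rescaling."""
    sym = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() >= eig_floor:
        out = sym
    else:
        vals = np.clip(vals, eig_floor, None)
        out = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


def _bandlimited_noise(
    rng: np.random.Generator, T: int, m: int, tr: float, band: tuple[float, float] | None
) -> np.ndarray:
    """Unit-variance white noise, optionally restricted to a frequency band."""
    white = rng.standard_normal((T, m))
    if band is None:
        return white
    low, high = band
    nyquist = 1.0 / (2.0 * tr)
    if not 0 < low < high < nyquist:
        raise ValueError(f"band must satisfy 0 < low < high < {nyquist} Hz")
    freqs = np.fft.rfftfreq(T, d=tr)
    mask = (freqs >= low) & (freqs <= high)
    if not mask.any():
        raise ValueError("band keeps no Fourier frequencies at this T and tr")
    spec = np.fft.rfft(white, axis=0)
    spec[~mask] = 0.0
    filtered = np.fft.irfft(spec, n=T, axis=0)
    sd = filtered.std(axis=0)
    sd[sd == 0] = 1.0
    return (filtered - filtered.mean(axis=0)) / sd


def simulate_timeseries(
    subjects: pd.DataFrame,
    annotation: pd.DataFrame,
    effects: EffectSpec,
    T: int = 360,
    tr: float = 1.0,
    band: tuple[float, float] | None = (0.008, 0.15),
    seed: int = 0,
) -> TimeseriesPanel:
    """Band-limited Gaussian ROI series with subject-specific correlations.

    Each subject's target node-node correlation matrix is obtained from the
    same Fisher-Z edge model as :func:`simulate_connectomes` (the noise draw
    acting as between-subject variability), mapped through tanh, repaired to
    the nearest correlation matrix, and imposed on independently filtered
    unit-variance noise so the population correlation equals the target.
    Defaults reflect a 6-minute scan sampled once per second.
    """
    if T < 2:
        raise ValueError("T must be at least 2")
    index = EdgeIndex(len(annotation))
    m = index.m
    rng = np.random.default_rng(seed)
    z = _subject_mean_z(subjects, effects, index.n_edges)
    if effects.noise_sd > 0:
        z += rng.normal(0.0, effects.noise_sd, size=z.shape)
    n = len(subjects)
    series = np.empty((n, T, m))
    for s in range(n):
        target = index.to_matrix(np.tanh(z[s]), diag=1.0)
        target = nearest_correlation(target)
        L = np.linalg.cholesky(target + 1e-12 * np.eye(m))
        noise = _bandlimited_noise(rng, T, m, tr, band)
        series[s] = noise @ L.T
    return TimeseriesPanel(series, tr, band, subjects["subject_id"].astype(str).tolist())


def write_subjects(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=SUBJECT_COLUMNS)


def read_subjects(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"subject table missing columns {missing}")
    if df[SUBJECT_COLUMNS].isna().any().any():
        raise ValueError("subject table has missing values (complete-case required)")
    return df[SUBJECT_COLUMNS]


def write_annotation(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=NODE_COLUMNS)


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in NODE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation missing columns {missing}")
    node_ids = df["node_id"].to_numpy()
    if not np.array_equal(np.sort(node_ids), np.arange(len(df))):
        raise ValueError("node_id values must be unique and contiguous from 0")
    return df.sort_values("node_id").reset_index(drop=True)[NODE_COLUMNS]
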