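"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates what a real melanoma expression + survival study
provides, so every stage runs with no downloads:

* per-gene log-normal expression on an FPKM-like scale, with a point
  mass of exact zeros (default 5%) so tie handling is exercised routinely;
* a set of designated "true" gene pairs whose within-sample order
  indicators drive survival through a proportional-hazards linear
  predictor eta = sum_k beta_k 1[expr_a > expr_b];
* survival times drawn by inverse transform from an exponential or
  Weibull baseline with hazard proportional to exp(eta);
* independent uniform censoring, calibrated by bisection so the realised
  censoring fraction matches the target;
* binary mutation flags, optionally associated with eta; and
* per-sample strictly monotone platform distortions (affine or power)
  that change every value but no within-sample ordering — the condition
  under which a rank-pair classifier must be invariant.

True pairs are built from disjoint genes that share a log-normal location
so their indicator is balanced (otherwise it would be filtered as
near-constant and no signature could recover it).
"""

from __future__ import annotations

from collections.abc import Callable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signature import GenePair

__all__ = [
    "SimulationConfig",
    "simulate_cohort",
    "apply_platform_distortion",
    "simulate_cell_fractions",
]


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    Defaults describe a desk-scale prognostic study: 300 patients, 100
    immune genes, three prognostic pairs with log hazard ratios
    (1.2, -1.2, 1.2), a Weibull baseline with ~30-month median survival,
    and a 30% censoring target. The pair effects make the cohort a
    positive control: large enough that the stringent p < 1e-4 candidate
    screen retains every true pair at this sample size, so pipeline
    defects — not sampling noise — are what recovery failures indicate.
    """

    n_samples: int = 300
    n_genes: int = 100
    n_true_pairs: int = 3
    betas: Sequence[float] = (1.2, -1.2, 1.2)
    survival_family: str = "weibull"  # or "exponential"
    baseline_hazard: float = 0.0117  # Weibull rate: median ~30 months at eta=0
    weibull_shape: float = 1.2
    censoring_fraction: float = 0.30
    expression_location_mean: float = 2.0  # natural-log scale
    expression_location_sd: float = 0.5
    expression_scale_range: tuple[float, float] = (0.4, 1.0)
    tie_zero_fraction: float = 0.05
    mutation_freq: Mapping[str, float] = field(default_factory=lambda: {"braf_mut": 0.4, "nras_mut": 0.23})
    mutation_score_assoc: float = 0.0  # log-odds of mutation per unit eta (centred)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.betas) != self.n_true_pairs:
            raise ValueError("betas must have one entry per true pair")
        if not all(np.isfinite(self.betas)):
            raise ValueError("effect sizes must be finite")
        if not 0 <= self.censoring_fraction < 1:
            raise ValueError("censoring fraction must lie in [0, 1)")
        if 2 * self.n_true_pairs > self.n_genes:
            raise ValueError("need two distinct genes per true pair")
        if self.survival_family not in ("weibull", "exponential"):
            raise ValueError(f"unknown survival family {self.survival_family!r}")


def _draw_survival_times(rng: np.random.Generator, eta: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Inverse-transform sampling from S(t|eta) with hazard prop. to exp(eta).

    Exponential: T = -log U / (lam * e^eta).
    Weibull (shape k): S(t) = exp(-lam t^k e^eta) => T = (-log U / (lam e^eta))^(1/k).
    """
    u = rng.uniform(size=eta.size)
    scale = -np.log(u) / (config.baseline_hazard * np.exp(eta))
    if config.survival_family == "exponential":
        return scale
    return scale ** (1.0 / config.weibull_shape)


def _calibrate_censoring(latent: np.ndarray, target: float) -> float:
    """Upper bound c_max of Uniform(0, c_max) censoring matching ``target``.

    With C ~ U(0, c_max), P(censored) = E[min(T, c_max)] / c_max, which
    decreases continuously from 1 to 0 in c_max; solved by bisection on
    the realised event times.
    """
    if target <= 0:
        return np.inf

    def frac(c: float) -> float:
        return float(np.minimum(latent, c).mean() / c)

    lo, hi = 1e-6, float(latent.max()) * 2
    while frac(hi) > target:
        hi *= 2
        if hi > 1e12:
            raise ValueError(f"censoring target {target} infeasible for these survival times")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Draw an (expression, survival, truth) triple under ``config``.

    All randomness flows through one generator seeded by ``config.seed``,
    so the same config is bit-reproducible. The truth record carries the
    designated pairs, their effect sizes, the per-sample linear predictor
    and the calibrated censoring bound.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:04d}" for i in range(1, config.n_genes + 1)]
    samples = [f"S{i:04d}" for i in range(1, config.n_samples + 1)]

    mu = rng.normal(config.expression_location_mean, config.expression_location_sd, size=config.n_genes)
    sigma = rng.uniform(*config.expression_scale_range, size=config.n_genes)
    # true pairs use disjoint genes with matched location and scale so the
    # order indicator is near-balanced across samples
    pair_gene_idx = rng.choice(config.n_genes, size=2 * config.n_true_pairs, replace=False)
    true_pairs: list[GenePair] = []
    for k in range(config.n_true_pairs):
        ia, ib = pair_gene_idx[2 * k], pair_gene_idx[2 * k + 1]
        mu[ib] = mu[ia]
        sigma[ib] = sigma[ia]
        true_pairs.append(GenePair(genes[ia], genes[ib]))

    log_expr = mu[:, None] + sigma[:, None] * rng.standard_normal((config.n_genes, config.n_samples))
    values = np.exp(log_expr)
    if config.tie_zero_fraction > 0:
        values[rng.uniform(size=values.shape) < config.tie_zero_fraction] = 0.0
    expression = pd.DataFrame(values, index=genes, columns=samples)
    expression.index.name = "gene"

    indicator = np.stack(
        [
            (expression.loc[p.gene_a].to_numpy() > expression.loc[p.gene_b].to_numpy()).astype(float)
            for p in true_pairs
        ]
    ) if true_pairs else np.zeros((0, config.n_samples))
    eta = np.asarray(config.betas, dtype=float) @ indicator if true_pairs else np.zeros(config.n_samples)

    latent = _draw_survival_times(rng, eta, config)
    c_max = _calibrate_censoring(latent, config.censoring_fraction)
    censor = rng.uniform(0.0, c_max, size=latent.size) if np.isfinite(c_max) else np.full(latent.size, np.inf)
    os_time = np.minimum(latent, censor)
    event = (latent <= censor).astype(int)
    os_time = np.maximum(os_time, 1e-6)  # os_time strictly positive

    clinical = pd.DataFrame(
        {
            "os_time": os_time,
            "event": event,
            "age": np.round(rng.normal(58.0, 13.0, size=len(samples))).clip(18, 95),
            "gender": rng.integers(0, 2, size=len(samples)),
            "stage": rng.integers(1, 5, size=len(samples)),
        },
        index=pd.Index(samples, name="sample_id"),
    )
    eta_centred = eta - eta.mean()
    for flag, freq in config.mutation_freq.items():
        logit = np.log(freq / (1.0 - freq)) + config.mutation_score_assoc * eta_centred
        clinical[flag] = (rng.uniform(size=len(samples)) < 1.0 / (1.0 + np.exp(-logit))).astype(int)

    truth = {
        "true_pairs": [p.pair_id for p in true_pairs],
        "betas": list(map(float, config.betas)),
        "eta": pd.Series(eta, index=samples, name="eta"),
        "latent_times": latent,
        "censoring_upper_bound": float(c_max) if np.isfinite(c_max) else None,
        "realized_censoring": float(1.0 - event.mean()),
        "seed": config.seed,
    }
    return expression, clinical, truth


def apply_platform_distortion(
    matrix: pd.DataFrame,
    family: str | Sequence[Callable[[np.ndarray], np.ndarray]] = "affine",
    seed: int = 0,
) -> pd.DataFrame:
    """Transform each sample column by its own strictly increasing map.

    ``family`` is ``"affine"`` (x -> a x + b, a ~ U(0.5, 2), b ~ U(0, 0.5)),
    ``"power"`` (x -> x^p, p ~ U(0.5, 2); monotone on non-negative data and
    fixing the zero tie mass), or an explicit list of per-sample callables.
    Callables are spot-checked for monotonicity on the column's sorted
    values; a non-monotone map is an error. Within-sample ranks — hence
    every pair score downstream — are unchanged.
    """
    rng = np.random.default_rng(seed)
    values = matrix.to_numpy(dtype=float)
    out = np.empty_like(values)
    n_samples = values.shape[1]
    if isinstance(family, str):
        if family == "affine":
            a = rng.uniform(0.5, 2.0, size=n_samples)
            b = rng.uniform(0.0, 0.5, size=n_samples)
            out = values * a[None, :] + b[None, :]
        elif family == "power":
            p = rng.uniform(0.5, 2.0, size=n_samples)
            out = values ** p[None, :]
        else:
            raise ValueError(f"unknown distortion family {family!r}")
    else:
        maps = list(family)
        if len(maps) != n_samples:
            raise ValueError("need one map per sample")
        for j, fn in enumerate(maps):
            col = values[:, j]
            transformed = np.asarray(fn(col), dtype=float)
            order = np.argsort(col, kind="stable")
            diffs_in = np.diff(col[order])
            diffs_out = np.diff(transformed[order])
            if np.any((diffs_in > 0) & (diffs_out <= 0)) or np.any((diffs_in == 0) & (diffs_out != 0)):
                raise ValueError(f"map for sample {matrix.columns[j]!r} is not strictly increasing")
            out[:, j] = transformed
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def simulate_cell_fractions(
    groups: pd.Series,
    n_features: int = 22,
    concentration: float | Sequence[float] = 2.0,
    shifts: Mapping[str, Mapping[str, float] | float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Dirichlet cell-type compositions per sample, with optional group shifts.

    Each sample's fractions are Dirichlet with base concentration
    ``concentration`` per cell type (scalar, or one value per type to give
    some types dominant abundance); ``shifts`` maps feature name to a
    log-concentration offset (scalar applied to the 'high' group, or a
    {group: offset} mapping). Rows sum to one exactly.
    """
    rng = np.random.default_rng(seed)
    features = [f"CellType{i:02d}" for i in range(1, n_features + 1)]
    if np.ndim(concentration) == 0:
        alpha_base = np.full(n_features, float(concentration))
    else:
        alpha_base = np.asarray(concentration, dtype=float)
        if alpha_base.size != n_features:
            raise ValueError("need one concentration per cell type")
    rows = np.empty((len(groups), n_features))
    for i, g in enumerate(groups):
        alpha = alpha_base.copy()
        if shifts:
            for feat, shift in shifts.items():
                j = features.index(feat)
                offset = shift.get(g, 0.0) if isinstance(shift, Mapping) else (shift if g == "high" else 0.0)
                alpha[j] = alpha[j] * np.exp(offset)
        rows[i] = rng.dirichlet(alpha)
    return pd.DataFrame(rows, index=groups.index, columns=features)
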