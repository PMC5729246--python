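"""Bottom-up prediction of interconnected circuits with confidence bands.

Test-set circuits are never refitted: their outputs are predicted by
composing the block parameters learned on the training set, propagating
estimation uncertainty by evaluating the steady-state model for every
parameter vector of a Monte Carlo (bootstrap) distribution and summarising
pointwise percentiles per HSL.  Sensitivity analyses replace the estimated
distribution with Gaussian perturbations (CV 25 % by default, so the 95 %
interval of a parameter p is roughly 0.5p..1.5p), either independently per
parameter class (univariate) or jointly with the estimated correlation
structure (multivariate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .circuits import CircuitTopology
from .fitting import ParameterDistribution
from .params import CascadeParameters
from .steady_state import ConvergenceError, cascade_outputs

logger = logging.getLogger(__name__)

HILL_PARAM_CLASSES = ("delta", "alpha", "K", "eta")


@dataclass
class PredictionBands:
    """Pointwise percentile summaries of predicted outputs per HSL."""

    circuit_id: str
    model: str
    hsl: np.ndarray
    bands: pd.DataFrame  # hsl_nM, observable, lower, median, upper
    n_draws: int
    n_failed: int = 0
    draws: dict[str, np.ndarray] = field(default_factory=dict)  # observable -> (n_draws, n_hsl)
    parameter_samples: pd.DataFrame | None = None  # draws that produced the bands

    def for_observable(self, observable: str) -> pd.DataFrame:
        out = self.bands[self.bands["observable"] == observable]
        if out.empty:
            raise KeyError(f"no {observable} bands")
        return out.reset_index(drop=True)


def _hsl_key(h: float) -> float:
    # normalise to 10 significant digits so CSV round-tripped grids still match
    return float(f"{float(h):.10g}")


def _mu_for(topo, hsl, growth_rates) -> np.ndarray:
    if callable(growth_rates):
        return np.array([growth_rates(topo.circuit_id, float(h)) for h in hsl])
    if isinstance(growth_rates, pd.DataFrame):
        items = (
            ((r["circuit_id"], r["hsl_nM"]), r["mu"]) for _, r in growth_rates.iterrows()
        )
    else:
        items = growth_rates.items()
    lut = {(cid, _hsl_key(h)): float(m) for (cid, h), m in items}
    return np.array([lut[(topo.circuit_id, _hsl_key(h))] for h in hsl])


def predict_circuit(
    topo: CircuitTopology,
    distribution: ParameterDistribution | pd.DataFrame,
    template: CascadeParameters,
    growth_rates,
    hsl_grid,
    model: str = "NBM",
    percentiles: tuple[float, float] = (2.5, 97.5),
    keep_draws: bool = True,
) -> PredictionBands:
    """Monte Carlo prediction bands for one circuit over an HSL grid.

    Each row of the parameter distribution is substituted into ``template``
    and the steady state evaluated over the grid with the externally fixed
    growth rates; percentile summaries are pointwise per HSL.  Draws whose
    burden fixed point fails to converge are dropped and counted.
    """
    samples = distribution.samples if isinstance(distribution, ParameterDistribution) else distribution
    if samples.empty:
        raise ValueError("empty parameter distribution")
    hsl = np.asarray(hsl_grid, dtype=float)
    mu = _mu_for(topo, hsl, growth_rates)
    draws: dict[str, list[np.ndarray]] = {}
    n_failed = 0
    for _, row in samples.iterrows():
        params = template.updated({k: v for k, v in row.items() if np.isfinite(v)})
        try:
            out = cascade_outputs(topo, hsl, mu, params, model)
        except ConvergenceError:
            n_failed += 1
            continue
        for obs in ("RFP", "GFP"):
            if out[obs] is not None:
                draws.setdefault(obs, []).append(out[obs])
    if not draws:
        raise RuntimeError(f"all {len(samples)} draws failed for {topo.circuit_id}")
    if n_failed:
        logger.info("%s: dropped %d non-converged draws", topo.circuit_id, n_failed)

    records = []
    stacked = {obs: np.vstack(v) for obs, v in draws.items()}
    for obs, mat in stacked.items():
        lo = np.percentile(mat, percentiles[0], axis=0)
        med = np.percentile(mat, 50.0, axis=0)
        hi = np.percentile(mat, percentiles[1], axis=0)
        for k, h in enumerate(hsl):
            records.append(
                dict(hsl_nM=float(h), observable=obs, lower=lo[k], median=med[k], upper=hi[k])
            )
    return PredictionBands(
        circuit_id=topo.circuit_id,
        model=model,
        hsl=hsl,
        bands=pd.DataFrame(records),
        n_draws=len(samples) - n_failed,
        n_failed=n_failed,
        draws=stacked if keep_draws else {},
    )


@dataclass
class SensitivitySpec:
    mode: str = "univariate"  # or "multivariate"
    cv: float = 0.25
    n_draws: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv <= 0:
            raise ValueError("sensitivity CV must be positive")


def _positive_normal(rng, mean, sd, size):
    """Gaussian draws with negatives rejected and resampled."""
    out = rng.normal(mean, sd, size)
    bad = out <= 0
    for _ in range(1000):
        if not np.any(bad):
            return out
        out[bad] = rng.normal(np.broadcast_to(mean, out.shape)[bad], np.broadcast_to(sd, out.shape)[bad])
        bad = out <= 0
    raise RuntimeError("could not draw positive parameter values")


def sensitivity_univariate(
    topo: CircuitTopology,
    base_params: CascadeParameters,
    target: str,
    spec: SensitivitySpec,
    growth_rates,
    hsl_grid,
    model: str = "NBM",
) -> PredictionBands:
    """Perturb one Hill parameter class (delta/alpha/K/eta) across all of a
    circuit's blocks with independent Gaussians (mean = estimate, CV =
    ``spec.cv``), holding everything else fixed."""
    if target not in HILL_PARAM_CLASSES:
        raise ValueError(f"target must be one of {HILL_PARAM_CLASSES}")
    rng = np.random.default_rng(spec.seed)
    flat = base_params.to_flat()
    names = [f"{dev}.{target}" for dev in topo.devices]
    cols = {}
    for name in names:
        mean = flat[name]
        cols[name] = _positive_normal(rng, mean, spec.cv * mean, spec.n_draws)
    samples = pd.DataFrame(cols)
    bands = predict_circuit(topo, samples, base_params, growth_rates, hsl_grid, model)
    bands.parameter_samples = samples
    return bands


def sensitivity_multivariate(
    topo: CircuitTopology,
    distribution: ParameterDistribution,
    base_params: CascadeParameters,
    spec: SensitivitySpec,
    growth_rates,
    hsl_grid,
    model: str = "NBM",
) -> PredictionBands:
    """Joint Gaussian perturbation of all the circuit's Hill parameters with
    the empirical correlation of the Monte Carlo sample.

    The correlation matrix is repaired by eigenvalue clipping if it is not
    positive semi-definite; negative draws are rejected and resampled.
    """
    names = [
        f"{dev}.{p}"
        for dev in topo.devices
        for p in HILL_PARAM_CLASSES
        if f"{dev}.{p}" in distribution.samples.columns
    ]
    if not names:
        raise ValueError("distribution contains none of the circuit's parameters")
    means = distribution.median()[names].to_numpy(float)
    corr = distribution.corr().loc[names, names].to_numpy(float)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    # PSD repair by eigenvalue clipping
    w, v = np.linalg.eigh(corr)
    if np.min(w) < 0:
        logger.info("clipping %d negative correlation eigenvalues", int((w < 0).sum()))
        w = np.clip(w, 1e-10, None)
        corr = v @ np.diag(w) @ v.T
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
    if np.min(np.linalg.eigvalsh(corr)) < -1e-8:
        raise ValueError("correlation matrix not PSD after repair")
    sd = spec.cv * means
    cov = corr * np.outer(sd, sd)
    rng = np.random.default_rng(spec.seed)
    draws = rng.multivariate_normal(means, cov, size=spec.n_draws, method="eigh")
    bad = np.any(draws <= 0, axis=1)
    for _ in range(1000):
        if not bad.any():
            break
        draws[bad] = rng.multivariate_normal(means, cov, size=int(bad.sum()), method="eigh")
        bad = np.any(draws <= 0, axis=1)
    samples = pd.DataFrame(draws, columns=names)
    bands = predict_circuit(topo, samples, base_params, growth_rates, hsl_grid, model)
    bands.parameter_samples = samples
    return bands


def prediction_performance(
    observed: pd.DataFrame, predicted: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation of observed vs predicted central values.

    Inputs are tidy frames with columns (circuit_id, hsl_nM, observable,
    value); rows are paired on the first three.  Returns (per-observable
    summary with r, p and n; merged scatter table).
    """
    keys = ["circuit_id", "hsl_nM", "observable"]
    merged = observed.merge(predicted, on=keys, suffixes=("_obs", "_pred"))
    if merged.empty:
        raise ValueError("no overlapping conditions between observed and predicted")
    summaries = []
    for obs, g in merged.groupby("observable"):
        if len(g) < 3:
            raise ValueError(f"fewer than 3 paired observations for {obs}")
        r, p = stats.pearsonr(g["value_obs"], g["value_pred"])
        summaries.append(dict(observable=obs, r=float(r), pvalue=float(p), n=len(g)))
    return pd.DataFrame(summaries), merged


def plot_bands(bands: PredictionBands, observed: pd.DataFrame | None = None, ax=None):
    """Dose-response plot with median curve and confidence bands."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    eps = None
    for obs, colour in (("RFP", "tab:red"), ("GFP", "tab:green")):
        try:
            b = bands.for_observable(obs)
        except KeyError:
            continue
        x = b["hsl_nM"].to_numpy(float)
        if eps is None:
            pos = x[x > 0]
            eps = pos.min() / 10 if len(pos) else 1.0
        x = np.where(x > 0, x, eps)
        ax.plot(x, b["median"], color=colour, label=f"{obs} median")
        ax.fill_between(x, b["lower"], b["upper"], color=colour, alpha=0.2)
        if observed is not None:
            o = observed[
                (observed["circuit_id"] == bands.circuit_id) & (observed["observable"] == obs)
            ]
            ax.plot(np.where(o["hsl_nM"] > 0, o["hsl_nM"], eps), o["value"], "o", color=colour)
    ax.set_xscale("log")
    ax.set_xlabel("HSL (nM)")
    ax.set_ylabel("output (normalised synthesis rate)")
    ax.set_title(bands.circuit_id)
    ax.legend(fontsize=8)
    return ax
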