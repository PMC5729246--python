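"""Weighted least-squares estimation of cascade parameters.

The estimation strategy follows the bottom-up characterisation of the
device collection: input blocks are learned first on their own measurement
circuits, then NOT gates with upstream parameters fixed (no-burden model)
or, for the burden model, the four input blocks are fitted simultaneously
together with the shared resource-usage parameters (J_RFP, the three Sigma
terms, S_m) before each NOT gate contributes its own J.  Every residual is
weighted by the reciprocal replicate variance of its condition.  Parameter
uncertainty is propagated by parametric bootstrap: synthetic datasets are
simulated at the point estimates with the per-condition noise, refitted,
and downstream fitting stages draw their upstream parameters from the
upstream bootstrap distribution.

Parameters are optimised in log10 space (positivity by construction) with a
seeded multistart around data-driven initial values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from . import circuits as circuits_mod
from .circuits import make_circuit_id
from .datasets import DoseResponseDataset
from .params import (
    BurdenParams,
    CascadeParameters,
    HillParams,
    default_parameters,
)
from .steady_state import ConvergenceError, cascade_outputs, hill_rate

logger = logging.getLogger(__name__)

INPUT_DEVICES = ("X_1", "X_2", "X_3", "X_rep")
#: gate device -> (input device of its training circuit, burden key)
GATE_TRAINING = {"T": ("X_2", "J_tet"), "L": ("X_3", "J_lac")}
BURDEN_KEYS = ("Sigma.lambda", "Sigma.lac", "Sigma.tet", "J_RFP", "J_tet", "J_lac", "S_m")
ETA_BOUNDS = (0.3, 10.0)


def neutral_parameters(with_burden: bool = False) -> CascadeParameters:
    """Structure-only parameter template: orientations and constants from the
    packaged registry, all values neutral placeholders."""
    ref = default_parameters("NBM_training")
    ref.hill.update(default_parameters("NBM_weak_tet").hill)
    hill = {
        name: HillParams(delta=0.1, alpha=1.0, K=10.0, eta=1.0, orientation=h.orientation)
        for name, h in ref.hill.items()
    }
    burden = BurdenParams(s_m=1.0) if with_burden else None
    return CascadeParameters(hill=hill, burden=burden, constants=ref.constants)


# ---------------------------------------------------------------------------
# fit specification and results


@dataclass
class FitSpec:
    """What to fit: model, free parameters, data slice and optimiser settings."""

    model: str
    free: list[str]
    circuits: list[str]
    observables: list[str] = field(default_factory=lambda: ["RFP"])
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    init: dict[str, float] = field(default_factory=dict)
    n_starts: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.free:
            raise ValueError("free parameter list must be non-empty")
        if len(set(self.free)) != len(self.free):
            raise ValueError("duplicate free parameters")


@dataclass
class FitResult:
    model: str
    free: list[str]
    params_flat: dict[str, float]
    params: CascadeParameters
    ssr: float
    success: bool
    message: str
    nfev: int
    rows: pd.DataFrame  # circuit_id, hsl_nM, replicate, observable, y, sigma, yhat, wres
    cv: dict[str, float]

    @property
    def n_data(self) -> int:
        return len(self.rows)


class _FitData:
    """Pre-indexed data slice: rows, per-condition sigma, per-circuit grids."""

    def __init__(self, data: DoseResponseDataset, circuits, observables, registry):
        df = data.df
        sel = df[df["circuit_id"].isin(circuits) & df["observable"].isin(observables)]
        if sel.empty:
            raise ValueError(f"no data for circuits={circuits} observables={observables}")
        missing = sorted(set(circuits) - set(sel["circuit_id"].unique()))
        if missing:
            raise ValueError(f"missing circuits in dataset: {missing}")
        sigma = (
            sel.groupby(["circuit_id", "hsl_nM", "observable"])["value"]
            .std(ddof=1)
            .fillna(0.0)
            .rename("sigma")
            .reset_index()
        )
        # weights replace degenerate zero sigma with the smallest positive one;
        # the raw replicate SD is kept for noise simulation (zero -> no noise)
        sigma["sigma_rep"] = sigma["sigma"]
        positive = sigma.loc[sigma["sigma"] > 0, "sigma"]
        floor = float(positive.min()) if len(positive) else 1.0
        sigma.loc[sigma["sigma"] <= 0, "sigma"] = floor
        sel = sel.merge(sigma, on=["circuit_id", "hsl_nM", "observable"], how="left")
        sel = sel.reset_index(drop=True)

        self.rows = sel
        self.y = sel["value"].to_numpy(float)
        self.sigma = sel["sigma"].to_numpy(float)
        self.grids = {}
        self.index = []  # (circuit_id, observable, row_idx, cond_pos)
        for cid, g in sel.groupby("circuit_id"):
            hsl_u = np.sort(g["hsl_nM"].unique())
            mu_u = g.groupby("hsl_nM")["mu"].mean().loc[hsl_u].to_numpy(float)
            self.grids[cid] = (registry[cid], hsl_u, mu_u)
            pos = {h: k for k, h in enumerate(hsl_u)}
            for obs, go in g.groupby("observable"):
                row_idx = go.index.to_numpy()
                cond_pos = np.array([pos[h] for h in go["hsl_nM"]], dtype=int)
                self.index.append((cid, obs, row_idx, cond_pos))

    def predict(self, params: CascadeParameters, model: str) -> np.ndarray:
        yhat = np.empty_like(self.y)
        cache = {}
        warm = getattr(self, "_dhat_warm", None)
        if warm is None:
            warm = self._dhat_warm = {}
        for cid, obs, row_idx, cond_pos in self.index:
            if cid not in cache:
                topo, hsl_u, mu_u = self.grids[cid]
                cache[cid] = cascade_outputs(
                    topo, hsl_u, mu_u, params, model, d0=warm.get(cid)
                )
                warm[cid] = cache[cid]["D_hat"]
            pred = cache[cid][obs]
            if pred is None:
                raise ValueError(f"model produces no {obs} output for circuit {cid}")
            yhat[row_idx] = pred[cond_pos]
        return yhat


_DEFAULT_BOUNDS = {
    "delta": (1e-6, 1e3),
    "alpha": (1e-4, 1e4),
    "eta": ETA_BOUNDS,
    "J": (1e-8, 10.0),
    "Sigma": (1e-8, 10.0),
    "S_m": (1e-4, 1e3),
}


def _bound_for(name: str, spec: FitSpec, fd: _FitData) -> tuple[float, float]:
    if name in spec.bounds:
        return spec.bounds[name]
    if name == "S_m":
        return _DEFAULT_BOUNDS["S_m"]
    if name.startswith("Sigma."):
        return _DEFAULT_BOUNDS["Sigma"]
    if name.startswith("J_"):
        return _DEFAULT_BOUNDS["J"]
    pname = name.split(".", 1)[1]
    if pname == "K":
        dev = name.split(".", 1)[0]
        if dev in INPUT_DEVICES:
            hsl = np.concatenate([fd.grids[c][1] for c in fd.grids])
            hsl = hsl[hsl > 0]
            return (float(hsl.min()) * 1e-2, float(hsl.max()) * 1e2)
        return (1e-3, 1e5)  # repressor-level input range
    return _DEFAULT_BOUNDS[pname]


def _default_init(name: str) -> float:
    if name == "S_m":
        return 1.0
    if name.startswith("Sigma."):
        return 0.3
    if name.startswith("J_"):
        return 0.05
    pname = name.split(".", 1)[1]
    return {"delta": 0.1, "alpha": 5.0, "K": 20.0, "eta": 1.2}[pname]


def wls_fit(
    spec: FitSpec,
    data: DoseResponseDataset,
    template: CascadeParameters,
    registry: dict | None = None,
) -> FitResult:
    """Minimise sum_i w_i (y_i - yhat_i)^2 with w_i = 1 / sigma_i^2.

    ``template`` supplies every parameter not listed free (and the global
    constants); growth rates are fixed to the per-condition dataset values.
    """
    registry = registry if registry is not None else circuits_mod.registry()
    fd = _FitData(data, spec.circuits, spec.observables, registry)
    template.updated({k: _default_init(k) for k in spec.free})  # key validation

    lo = np.log10([_bound_for(n, spec, fd)[0] for n in spec.free])
    hi = np.log10([_bound_for(n, spec, fd)[1] for n in spec.free])
    x0 = np.log10([spec.init.get(n, _default_init(n)) for n in spec.free])
    x0 = np.clip(x0, lo, hi)

    big = 1e8

    def residuals(x):
        params = template.updated({n: v for n, v in zip(spec.free, 10.0**x)})
        try:
            yhat = fd.predict(params, spec.model)
        except ConvergenceError:
            return np.full_like(fd.y, big)
        r = (fd.y - yhat) / fd.sigma
        return np.where(np.isfinite(r), r, big)

    rng = np.random.default_rng(spec.seed)
    starts = [x0]
    for _ in range(max(spec.n_starts - 1, 0)):
        starts.append(np.clip(x0 + rng.normal(0.0, 0.3, size=x0.shape), lo, hi))

    best = None
    for start in starts:
        sol = least_squares(residuals, start, bounds=(lo, hi), method="trf")
        if best is None or sol.cost < best.cost:
            best = sol
    logger.debug("wls_fit model=%s free=%d ssr=%.4g nfev=%d", spec.model, len(spec.free),
                 2 * best.cost, best.nfev)

    values = 10.0**best.x
    params_flat = {n: float(v) for n, v in zip(spec.free, values)}
    params = template.updated(params_flat)
    yhat = fd.predict(params, spec.model)
    wres = (fd.y - yhat) / fd.sigma
    rows = fd.rows[
        ["circuit_id", "hsl_nM", "replicate", "observable", "value", "sigma", "sigma_rep", "mu"]
    ]
    rows = rows.rename(columns={"value": "y"}).assign(yhat=yhat, wres=wres)

    # linearised per-parameter CV (descriptive; bootstrap gives the real one)
    cv = {}
    try:
        jac = best.jac
        dof = max(len(fd.y) - len(spec.free), 1)
        cov_log = np.linalg.pinv(jac.T @ jac) * (2 * best.cost / dof)
        se_log = np.sqrt(np.clip(np.diag(cov_log), 0, None))
        for n, v, s in zip(spec.free, values, se_log):
            cv[n] = float(np.log(10.0) * s)  # relative SE of the value
    except np.linalg.LinAlgError:
        pass

    return FitResult(
        model=spec.model,
        free=list(spec.free),
        params_flat=params_flat,
        params=params,
        ssr=float(np.sum(wres**2)),
        success=bool(best.success),
        message=str(best.message),
        nfev=int(best.nfev),
        rows=rows,
        cv=cv,
    )


# ---------------------------------------------------------------------------
# data-driven initial values


def _hill_init(device: str, fd_df: pd.DataFrame, consts, orientation: str,
               input_levels: np.ndarray | None = None) -> dict[str, float]:
    """Heuristic Hill start from condition means of one circuit's RFP data."""
    means = fd_df[fd_df["observable"] == "RFP"].groupby("hsl_nM")["value"].mean()
    mu_mean = float(fd_df["mu"].mean())
    scale = (mu_mean + consts.a) / consts.a  # invert output = a*S/(mu+a)
    s = means.to_numpy(float) * scale
    if input_levels is None:
        input_levels = means.index.to_numpy(float)
    pos = np.asarray(input_levels, float)
    pos = pos[pos > 0]
    k0 = float(np.exp(np.mean(np.log(pos)))) if len(pos) else 10.0
    return {
        f"{device}.delta": max(float(s.min()), 1e-3),
        f"{device}.alpha": max(float(s.max() - s.min()), 1e-3),
        f"{device}.K": k0,
        f"{device}.eta": 1.2,
    }


@dataclass
class TrainingFit:
    model: str
    params: CascadeParameters
    stage_fits: dict[str, FitResult]


def fit_training_nbm(
    data: DoseResponseDataset,
    registry: dict | None = None,
    monitor: bool = False,
    n_starts: int = 5,
    seed: int = 0,
    upstream_params: CascadeParameters | None = None,
    input_devices: tuple[str, ...] = INPUT_DEVICES,
    gates: dict[str, tuple[str, str]] | None = None,
) -> TrainingFit:
    """Sequential no-burden training fit.

    Stage 1: independent 4-parameter Hill fits on the input-block circuits
    (RFP).  Stage 2: each NOT gate fitted on its training circuit with the
    upstream input-block parameters fixed to the stage-1 estimates (or to
    ``upstream_params`` if supplied).  ``input_devices``/``gates`` restrict
    the stages to a subset of the collection.
    """
    registry = registry if registry is not None else circuits_mod.registry()
    gates = GATE_TRAINING if gates is None else gates
    template = neutral_parameters()
    consts = template.constants
    stage_fits: dict[str, FitResult] = {}

    for i, dev in enumerate(input_devices):
        cid = make_circuit_id(dev, (), monitor)
        if cid not in data.circuits:
            raise ValueError(f"training circuit {cid} missing from dataset")
        cdf = data.df[data.df["circuit_id"] == cid]
        spec = FitSpec(
            model="NBM",
            free=[f"{dev}.delta", f"{dev}.alpha", f"{dev}.K", f"{dev}.eta"],
            circuits=[cid],
            init=_hill_init(dev, cdf, consts, template.hill[dev].orientation),
            n_starts=n_starts,
            seed=seed + i,
        )
        fit = wls_fit(spec, data, template, registry)
        stage_fits[dev] = fit
        template = template.updated(fit.params_flat)

    if upstream_params is not None:
        template = template.updated(
            {
                f"{dev}.{p}": getattr(upstream_params.hill[dev], p)
                for dev in input_devices
                for p in ("delta", "alpha", "K", "eta")
            }
        )

    for j, (gate, (input_dev, _)) in enumerate(gates.items()):
        cid = make_circuit_id(input_dev, (gate,), monitor)
        if cid not in data.circuits:
            raise ValueError(f"training circuit {cid} missing from dataset")
        cdf = data.df[data.df["circuit_id"] == cid]
        # gate input levels: upstream repressor level over the HSL grid
        hsl_u = np.sort(cdf["hsl_nM"].unique())
        mu_u = cdf.groupby("hsl_nM")["mu"].mean().loc[hsl_u].to_numpy(float)
        gamma = getattr(consts, "gamma_tet" if gate in ("T", "Tw") else "gamma_lac")
        p_up = hill_rate(template.hill[input_dev], hsl_u) / (mu_u + gamma)
        spec = FitSpec(
            model="NBM",
            free=[f"{gate}.delta", f"{gate}.alpha", f"{gate}.K", f"{gate}.eta"],
            circuits=[cid],
            init=_hill_init(gate, cdf, consts, "repressible", input_levels=p_up),
            n_starts=n_starts,
            seed=seed + 100 + j,
        )
        fit = wls_fit(spec, data, template, registry)
        stage_fits[gate] = fit
        template = template.updated(fit.params_flat)

    return TrainingFit(model="NBM", params=template, stage_fits=stage_fits)


def fit_training_bm(
    data: DoseResponseDataset,
    registry: dict | None = None,
    monitor: bool = True,
    n_starts: int = 3,
    seed: int = 0,
) -> TrainingFit:
    """Sequential burden-model training fit on RFP + GFP data.

    Stage 1 fits the four input blocks simultaneously (16 Hill parameters
    plus J_RFP, the three Sigma terms and S_m); stage 2 learns each NOT
    gate's Hill parameters together with its usage weight (J_tet, J_lac)
    with the stage-1 values fixed.  The monitor-only culture (``Mon_rg``),
    when present in the data, joins stage 1 to anchor S_m (without it the
    Hill rates, Sigma terms and S_m share an exact scaling degeneracy).
    """
    registry = registry if registry is not None else circuits_mod.registry()
    template = neutral_parameters(with_burden=True)
    consts = template.constants
    input_ids = [make_circuit_id(dev, (), monitor) for dev in INPUT_DEVICES]
    if "Mon_rg" in data.circuits:
        input_ids = input_ids + ["Mon_rg"]
    for cid in input_ids[: len(INPUT_DEVICES)]:
        if cid not in data.circuits:
            raise ValueError(f"training circuit {cid} missing from dataset")
        if data.df[(data.df["circuit_id"] == cid) & (data.df["observable"] == "GFP")].empty:
            raise ValueError(f"burden-model fit requires GFP data for {cid}")

    # warm start: Hill shapes from quick no-burden per-block fits on RFP
    init: dict[str, float] = {}
    for dev, cid in zip(INPUT_DEVICES, input_ids):
        cdf = data.df[data.df["circuit_id"] == cid]
        h0 = _hill_init(dev, cdf, consts, template.hill[dev].orientation)
        h0[f"{dev}.alpha"] *= 1.5  # burden hides part of the dynamic range
        init.update(h0)
    gfp = data.df[(data.df["circuit_id"].isin(input_ids)) & (data.df["observable"] == "GFP")]
    mu_mean = float(gfp["mu"].mean())
    init["S_m"] = float(gfp["value"].mean()) * (mu_mean + consts.a_G) / consts.a_G * 1.5
    init.update({"Sigma.lambda": 0.3, "Sigma.lac": 0.3, "Sigma.tet": 0.3, "J_RFP": 0.05})

    free_stage1 = [
        f"{dev}.{p}" for dev in INPUT_DEVICES for p in ("delta", "alpha", "K", "eta")
    ] + ["Sigma.lambda", "Sigma.lac", "Sigma.tet", "J_RFP", "S_m"]
    spec1 = FitSpec(
        model="BM",
        free=free_stage1,
        circuits=input_ids,
        observables=["RFP", "GFP"],
        init=init,
        n_starts=n_starts,
        seed=seed,
    )
    fit1 = wls_fit(spec1, data, template, registry)
    template = template.updated(fit1.params_flat)
    stage_fits = {"input_blocks": fit1}

    for j, (gate, (input_dev, j_key)) in enumerate(GATE_TRAINING.items()):
        cid = make_circuit_id(input_dev, (gate,), monitor)
        if cid not in data.circuits:
            raise ValueError(f"training circuit {cid} missing from dataset")
        cdf = data.df[data.df["circuit_id"] == cid]
        hsl_u = np.sort(cdf["hsl_nM"].unique())
        mu_u = cdf.groupby("hsl_nM")["mu"].mean().loc[hsl_u].to_numpy(float)
        gamma = getattr(consts, "gamma_tet" if gate in ("T", "Tw") else "gamma_lac")
        p_up = hill_rate(template.hill[input_dev], hsl_u) / (mu_u + gamma)
        ginit = _hill_init(gate, cdf, consts, "repressible", input_levels=p_up)
        ginit[j_key] = 0.05
        spec = FitSpec(
            model="BM",
            free=[f"{gate}.delta", f"{gate}.alpha", f"{gate}.K", f"{gate}.eta", j_key],
            circuits=[cid],
            observables=["RFP", "GFP"],
            init=ginit,
            n_starts=n_starts,
            seed=seed + 200 + j,
        )
        fit = wls_fit(spec, data, template, registry)
        stage_fits[gate] = fit
        template = template.updated(fit.params_flat)

    return TrainingFit(model="BM", params=template, stage_fits=stage_fits)


def fit_simultaneous(
    data: DoseResponseDataset,
    model: str,
    registry: dict | None = None,
    circuits: list[str] | None = None,
    n_starts: int = 1,
    seed: int = 0,
    init_params: CascadeParameters | None = None,
) -> FitResult:
    """One joint WLS over every circuit (and observable) in the slice.

    Used for the no-burden vs burden model comparison.  The free set is all
    Hill parameters of the devices appearing in the circuits, plus - for the
    burden model - every burden parameter.  ``init_params`` (e.g. a
    sequential training fit) provides the starting point.
    """
    registry = registry if registry is not None else circuits_mod.registry()
    circuits = circuits if circuits is not None else data.circuits
    devices = sorted({d for cid in circuits for d in registry[cid].devices} - {"none"})
    free = [f"{d}.{p}" for d in devices for p in ("delta", "alpha", "K", "eta")]
    observables = ["RFP"]
    if model == "BM":
        free += list(BURDEN_KEYS)
        if any("Tw" in registry[cid].gates for cid in circuits):
            free.append("J_tet_w")
        has_gfp = not data.df[
            data.df["circuit_id"].isin(circuits) & (data.df["observable"] == "GFP")
        ].empty
        if has_gfp:
            observables = ["RFP", "GFP"]
    template = neutral_parameters(with_burden=(model == "BM"))
    init = {}
    if init_params is not None:
        flat = init_params.to_flat()
        init = {k: flat[k] for k in free if k in flat and flat[k] > 0}
    spec = FitSpec(
        model=model,
        free=free,
        circuits=list(circuits),
        observables=observables,
        init=init,
        n_starts=n_starts,
        seed=seed,
    )
    return wls_fit(spec, data, template, registry)


# ---------------------------------------------------------------------------
# Monte Carlo uncertainty (parametric bootstrap)


@dataclass
class ParameterDistribution:
    """Monte Carlo sample of fitted parameter vectors."""

    samples: pd.DataFrame  # n_datasets x n_params
    n_failed: int = 0

    def median(self) -> pd.Series:
        return self.samples.median()

    def ci(self, lower: float = 2.5, upper: float = 97.5) -> pd.DataFrame:
        q = self.samples.quantile([lower / 100.0, upper / 100.0]).T
        q.columns = ["lower", "upper"]
        return q

    def corr(self) -> pd.DataFrame:
        return self.samples.corr()

    def cv(self) -> pd.Series:
        return self.samples.std() / self.samples.median().abs()

    @classmethod
    def from_point(cls, flat: dict[str, float]) -> "ParameterDistribution":
        return cls(pd.DataFrame([flat]))


def _simulate_rows(rows: pd.DataFrame, rng) -> np.ndarray:
    """One synthetic replicate set: N(yhat, sigma) truncated at zero.

    Uses the raw replicate SD (zero SD simulates no noise); the floored
    sigma is a weighting device only.
    """
    sd = rows["sigma_rep" if "sigma_rep" in rows.columns else "sigma"].to_numpy(float)
    sim = rows["yhat"].to_numpy(float) + rng.normal(0.0, 1.0, len(rows)) * sd
    return np.clip(sim, 0.0, None)


def _dataset_from_rows(rows: pd.DataFrame, values: np.ndarray) -> DoseResponseDataset:
    df = rows.rename(columns={"y": "value"})[
        ["circuit_id", "hsl_nM", "replicate", "observable", "value", "mu"]
    ].copy()
    df["value"] = values
    return DoseResponseDataset(df)


def monte_carlo_uncertainty(
    fit: FitResult,
    spec: FitSpec,
    template: CascadeParameters,
    n_datasets: int,
    seed: int,
    registry: dict | None = None,
    max_failure_rate: float = 0.2,
) -> ParameterDistribution:
    """Parametric bootstrap around a converged fit.

    Simulates ``n_datasets`` datasets at the point estimates with the
    per-condition replicate noise (negatives truncated at zero), refits each
    starting from the point estimate, and collects the estimates.
    """
    if not fit.success:
        raise ValueError("base fit did not converge; refusing to bootstrap")
    rng = np.random.default_rng(seed)
    refit_spec = replace(spec, n_starts=1, init=dict(fit.params_flat))
    samples, n_failed = [], 0
    for b in range(n_datasets):
        sim = _dataset_from_rows(fit.rows, _simulate_rows(fit.rows, rng))
        try:
            res = wls_fit(refit_spec, sim, template, registry)
            if not res.success:
                raise RuntimeError(res.message)
            samples.append(res.params_flat)
        except (RuntimeError, ValueError) as exc:
            n_failed += 1
            logger.debug("bootstrap draw %d failed: %s", b, exc)
    if n_failed > max_failure_rate * n_datasets:
        raise RuntimeError(
            f"bootstrap failure rate {n_failed}/{n_datasets} exceeds {max_failure_rate:.0%}"
        )
    return ParameterDistribution(pd.DataFrame(samples), n_failed=n_failed)


def bootstrap_training_nbm(
    data: DoseResponseDataset,
    n_datasets: int = 200,
    seed: int = 0,
    registry: dict | None = None,
    monitor: bool = False,
    n_starts_point: int = 5,
) -> tuple[TrainingFit, ParameterDistribution]:
    """Two-stage no-burden bootstrap with upstream uncertainty propagation.

    Each draw refits the four input blocks on their own simulated datasets,
    then refits each NOT gate on simulated gate-circuit data with the
    upstream parameters set to that draw's stage-1 estimates, so downstream
    stages sample the upstream parameter distribution rather than fixing the
    point estimate.
    """
    registry = registry if registry is not None else circuits_mod.registry()
    point = fit_training_nbm(data, registry, monitor=monitor, n_starts=n_starts_point, seed=seed)
    rng = np.random.default_rng(seed + 1)

    stage1 = {dev: point.stage_fits[dev] for dev in INPUT_DEVICES}
    gates = {g: point.stage_fits[g] for g in GATE_TRAINING}
    samples, n_failed = [], 0
    for _b in range(n_datasets):
        draw: dict[str, float] = {}
        ok = True
        for dev, fit in stage1.items():
            sim = _dataset_from_rows(fit.rows, _simulate_rows(fit.rows, rng))
            spec = FitSpec(
                model="NBM", free=list(fit.free), circuits=[fit.rows["circuit_id"].iloc[0]],
                init=dict(fit.params_flat), n_starts=1, seed=0,
            )
            try:
                res = wls_fit(spec, sim, neutral_parameters(), registry)
                draw.update(res.params_flat)
            except (RuntimeError, ValueError):
                ok = False
                break
        if ok:
            template = neutral_parameters().updated(draw)
            for gate, fit in gates.items():
                sim = _dataset_from_rows(fit.rows, _simulate_rows(fit.rows, rng))
                spec = FitSpec(
                    model="NBM", free=list(fit.free),
                    circuits=[fit.rows["circuit_id"].iloc[0]],
                    init=dict(fit.params_flat), n_starts=1, seed=0,
                )
                try:
                    res = wls_fit(spec, sim, template, registry)
                    draw.update(res.params_flat)
                except (RuntimeError, ValueError):
                    ok = False
                    break
        if ok:
            samples.append(draw)
        else:
            n_failed += 1
    if n_failed > 0.2 * n_datasets:
        raise RuntimeError(f"bootstrap failure rate {n_failed}/{n_datasets} exceeds 20%")
    return point, ParameterDistribution(pd.DataFrame(samples), n_failed=n_failed)


def bootstrap_training_bm(
    data: DoseResponseDataset,
    n_datasets: int = 200,
    seed: int = 0,
    registry: dict | None = None,
    monitor: bool = True,
    n_starts_point: int = 3,
) -> tuple[TrainingFit, ParameterDistribution]:
    """Burden-model analogue of :func:`bootstrap_training_nbm`."""
    registry = registry if registry is not None else circuits_mod.registry()
    point = fit_training_bm(data, registry, monitor=monitor, n_starts=n_starts_point, seed=seed)
    rng = np.random.default_rng(seed + 1)
    fit1 = point.stage_fits["input_blocks"]
    samples, n_failed = [], 0
    for _b in range(n_datasets):
        draw: dict[str, float] = {}
        ok = True
        sim = _dataset_from_rows(fit1.rows, _simulate_rows(fit1.rows, rng))
        spec1 = FitSpec(
            model="BM", free=list(fit1.free),
            circuits=sorted(fit1.rows["circuit_id"].unique()),
            observables=["RFP", "GFP"], init=dict(fit1.params_flat), n_starts=1, seed=0,
        )
        try:
            res1 = wls_fit(spec1, sim, neutral_parameters(with_burden=True), registry)
            draw.update(res1.params_flat)
        except (RuntimeError, ValueError):
            ok = False
        if ok:
            template = neutral_parameters(with_burden=True).updated(draw)
            for gate in GATE_TRAINING:
                fit = point.stage_fits[gate]
                sim = _dataset_from_rows(fit.rows, _simulate_rows(fit.rows, rng))
                spec = FitSpec(
                    model="BM", free=list(fit.free),
                    circuits=[fit.rows["circuit_id"].iloc[0]],
                    observables=["RFP", "GFP"], init=dict(fit.params_flat), n_starts=1, seed=0,
                )
                try:
                    res = wls_fit(spec, sim, template, registry)
                    draw.update(res.params_flat)
                except (RuntimeError, ValueError):
                    ok = False
                    break
        if ok:
            samples.append(draw)
        else:
            n_failed += 1
    if n_failed > 0.2 * n_datasets:
        raise RuntimeError(f"bootstrap failure rate {n_failed}/{n_datasets} exceeds 20%")
    return point, ParameterDistribution(pd.DataFrame(samples), n_failed=n_failed)


def monte_carlo_recovery(
    n_datasets: int,
    seed: int,
    truth_column: str = "NBM_training",
    input_devices: tuple[str, ...] = ("X_1",),
    gates: dict[str, tuple[str, str]] | None = None,
    cv: float = 0.10,
    n_replicates: int = 3,
    hsl_grid: list[float] | None = None,
    n_starts: int = 2,
    registry: dict | None = None,
) -> ParameterDistribution:
    """Parameter-recovery Monte Carlo: repeated experiments at known truth.

    Simulates ``n_datasets`` independent no-burden dose-response datasets at
    the packaged ``truth_column`` parameters (study noise conditions:
    replicate Gaussian CV, negatives truncated at zero), runs the sequential
    fitting procedure on each, and collects the estimates.  The median of
    the resulting distribution measures the estimator's central recovery of
    the generating values; its spread, the single-experiment uncertainty.
    """
    from .simulate import GenerationSpec, generate_dose_response

    registry = registry if registry is not None else circuits_mod.registry()
    gates = {} if gates is None else gates
    circuits = [make_circuit_id(d, (), False) for d in input_devices]
    circuits += [make_circuit_id(ud, (g,), False) for g, (ud, _) in gates.items()]
    seeds = np.random.SeedSequence(seed).generate_state(n_datasets) & 0x7FFFFFFF
    samples, n_failed = [], 0
    for b in range(n_datasets):
        gen = GenerationSpec(
            seed=int(seeds[b]),
            model="NBM",
            truth_column=truth_column,
            circuits=circuits,
            cv=cv,
            n_replicates=n_replicates,
            **({"hsl_grid": hsl_grid} if hsl_grid is not None else {}),
        )
        data = generate_dose_response(gen)
        try:
            fit = fit_training_nbm(
                data, registry, n_starts=n_starts, seed=int(seeds[b]) + 1,
                input_devices=input_devices, gates=gates,
            )
            flat = {}
            for f in fit.stage_fits.values():
                flat.update(f.params_flat)
            samples.append(flat)
        except (RuntimeError, ValueError):
            n_failed += 1
    if n_failed > 0.2 * n_datasets:
        raise RuntimeError(f"recovery failure rate {n_failed}/{n_datasets} exceeds 20%")
    return ParameterDistribution(pd.DataFrame(samples), n_failed=n_failed)


# ---------------------------------------------------------------------------
# likelihood and model comparison


def log_likelihood(fit: FitResult, observable: str = "RFP", formula: str = "as_reported") -> float:
    """Log-likelihood of a fit on one observable's residuals.

    ``as_reported`` uses LL = -(sqrt(2*pi) * sum_i sigma_i + 1/2 sum_i r_i^2)
    with r_i the weighted residuals, matching the form used alongside the
    likelihood-ratio comparison in the source analysis; ``gaussian`` is the
    textbook independent-Gaussian log-likelihood.  With a shared noise model
    the LR statistic depends only on the residual term either way.
    """
    rows = fit.rows[fit.rows["observable"] == observable]
    if rows.empty:
        raise ValueError(f"fit contains no {observable} rows")
    sigma = rows["sigma"].to_numpy(float)
    wres = rows["wres"].to_numpy(float)
    if formula == "as_reported":
        return float(-(np.sqrt(2 * np.pi) * sigma.sum() + 0.5 * np.sum(wres**2)))
    if formula == "gaussian":
        n = len(sigma)
        return float(-0.5 * n * np.log(2 * np.pi) - np.sum(np.log(sigma)) - 0.5 * np.sum(wres**2))
    raise ValueError("formula must be 'as_reported' or 'gaussian'")


@dataclass
class LRTestResult:
    statistic: float
    df: int
    pvalue: float
    ll_null: float
    ll_alt: float


def lr_test(fit_null: FitResult, fit_alt: FitResult, observable: str = "RFP",
            formula: str = "as_reported") -> LRTestResult:
    """Likelihood-ratio test of nested fits (null within alternative)."""
    if not set(fit_null.free) <= set(fit_alt.free):
        raise ValueError("models are not nested: null free set not within alternative's")
    keys = ["circuit_id", "hsl_nM", "replicate"]
    rn = fit_null.rows[fit_null.rows["observable"] == observable][keys]
    ra = fit_alt.rows[fit_alt.rows["observable"] == observable][keys]
    if len(rn) != len(ra) or not rn.sort_values(keys).reset_index(drop=True).equals(
        ra.sort_values(keys).reset_index(drop=True)
    ):
        raise ValueError("fits cover different data slices")
    ll0 = log_likelihood(fit_null, observable, formula)
    ll1 = log_likelihood(fit_alt, observable, formula)
    df = len(fit_alt.free) - len(fit_null.free)
    statistic = 2.0 * (ll1 - ll0)
    pvalue = float(stats.chi2.sf(max(statistic, 0.0), df)) if df > 0 else 1.0
    return LRTestResult(statistic=float(statistic), df=df, pvalue=pvalue, ll_null=ll0, ll_alt=ll1)
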