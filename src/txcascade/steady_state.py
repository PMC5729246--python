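"""Steady-state evaluation of transcriptional cascades.

Two nested models of the same cascade are implemented.  In the no-burden
model (NBM) every block's synthesis rate is a Hill function of its input and
blocks compose independently: a repressor reaches level P = S/(mu+gamma)
(dilution by growth plus LVA-tag degradation), the immature reporter
R = S/(mu+a), and the measured output is the mature-protein synthesis rate
a*R.  The burden model (BM) couples all blocks through a shared
gene-expression capacity: every realised synthesis rate is the Hill maximum
divided by a common denominator

    D_hat = 1 + Sigma_input + sum_k J_k * S_max,k

summed over the circuit-borne regulated genes (tetR, lacI, RFP).  The LuxR
cassette of the input block enters only through the lumped constant Sigma;
the constitutive GFP monitor is folded into the host term and does not load
D_hat, but its own output is scaled by it, which is what makes it a burden
sensor.  Because downstream S_max values depend on protein levels that are
themselves scaled by D_hat, the steady state is implicit and is solved by
damped fixed-point iteration; an ODE integration of the underlying kinetics
is provided as an independent oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .circuits import CircuitTopology
from .params import GATE_INFO, CascadeParameters, HillParams

__all__ = [
    "Condition",
    "SteadyStateResult",
    "ConvergenceError",
    "hill_rate",
    "cascade_outputs",
    "nbm_steady_state",
    "bm_steady_state",
    "ode_reference_steady_state",
    "classify_logic_behaviour",
    "LogicClassification",
]


class ConvergenceError(RuntimeError):
    """Fixed-point iteration failed to reach the requested tolerance."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class Condition:
    """External condition: inducer concentration and fixed growth rate."""

    hsl: float  # nM
    mu: float  # min^-1

    def __post_init__(self) -> None:
        if not np.isfinite(self.hsl) or self.hsl < 0:
            raise ValueError("HSL concentration must be finite and >= 0")
        if not np.isfinite(self.mu) or self.mu <= 0:
            raise ValueError("growth rate must be finite and > 0")


@dataclass
class SteadyStateResult:
    """Per-block rates and levels at the converged steady state.

    ``s_max`` holds the maximum (capacity-free) synthesis rate of each
    circuit-regulated gene in cascade order (first gate's repressor, ...,
    RFP); ``s`` the realised rates ``s_max / D_hat``; ``protein`` the
    repressor levels feeding each NOT gate.
    """

    circuit_id: str
    model: str
    d_hat: float
    s_max: list[float]
    s: list[float]
    protein: list[float]
    R: float
    s_cell_norm_rfp: float
    G: float | None = None
    s_cell_norm_gfp: float | None = None


def hill_rate(hill: HillParams, input_level):
    """Synthesis rate delta + alpha / (1 + (K/I)^(+-eta)).

    The exponent is +eta for an inducible promoter and -eta for a repressible
    one.  At I = 0 the analytic limit is used: delta (inducible, fully off)
    or delta + alpha (repressible, fully unrepressed).
    """
    I = np.asarray(input_level, dtype=float)
    if not np.all(np.isfinite(I)) or np.any(I < 0):
        raise ValueError("input level must be finite and >= 0")
    scalar = I.ndim == 0
    I = np.atleast_1d(I)
    out = np.empty_like(I)
    zero = I == 0.0
    limit = hill.delta if hill.orientation == "inducible" else hill.delta + hill.alpha
    out[zero] = limit
    if np.any(~zero):
        exponent = hill.eta if hill.orientation == "inducible" else -hill.eta
        with np.errstate(over="ignore"):
            ratio_pow = (hill.K / I[~zero]) ** exponent
        out[~zero] = hill.delta + hill.alpha / (1.0 + ratio_pow)
    return float(out[0]) if scalar else out


def _chain(topo, hsl, mu, params, d_hat):
    """Evaluate the cascade's S_max chain given the current denominator.

    Returns (s_max list, protein-level list).  ``s_max[k]`` is the capacity-
    free synthesis rate of the k-th regulated gene (gates' repressors in
    order, then RFP).
    """
    consts = params.constants
    if topo.input_device == "none":  # monitor-only strain: no circuit expression
        rate = np.zeros_like(np.asarray(hsl, dtype=float) * np.asarray(mu, dtype=float))
    else:
        rate = hill_rate(params.hill[topo.input_device], hsl)
    s_max = [rate]
    protein = []
    for gate in topo.gates:
        gamma = getattr(consts, GATE_INFO[gate][0])
        p = rate / (d_hat * (mu + gamma))
        protein.append(p)
        rate = hill_rate(params.hill[gate], p)
        s_max.append(rate)
    return s_max, protein


def _gene_loads(topo, params):
    """Usage weights J_k of the circuit-regulated genes, in cascade order."""
    burden = params.burden
    return [burden.J_for_gate(g) for g in topo.gates] + [burden.J_RFP]


def cascade_outputs(
    topo: CircuitTopology,
    hsl,
    mu,
    params: CascadeParameters,
    model: str = "NBM",
    tol: float = 1e-9,
    max_iter: int = 10_000,
    d0: np.ndarray | None = None,
) -> dict:
    """Vectorised steady-state outputs over arrays of conditions.

    Returns ``{"RFP": array, "GFP": array-or-None, "D_hat": array}`` with the
    measured observables (mature-protein synthesis rates per cell).  ``d0``
    warm-starts the burden fixed point (used by the fitters, where
    successive evaluations differ only slightly).
    """
    hsl = np.atleast_1d(np.asarray(hsl, dtype=float))
    mu = np.broadcast_to(np.asarray(mu, dtype=float), hsl.shape).astype(float)
    consts = params.constants

    if model == "NBM":
        d_hat = np.ones_like(hsl)
        s_max, _ = _chain(topo, hsl, mu, params, d_hat)
    elif model == "BM":
        if params.burden is None:
            raise ValueError("BM evaluation requires burden parameters")
        sigma = params.burden.sigma.get(topo.sigma_class, 0.0)
        loads = _gene_loads(topo, params)
        d_hat = np.ones_like(hsl) if d0 is None else np.array(d0, dtype=float)
        prev_res = None
        for _it in range(max_iter):
            s_max, _ = _chain(topo, hsl, mu, params, d_hat)
            target = 1.0 + sigma + sum(J * s for J, s in zip(loads, s_max))
            res = target - d_hat
            if np.max(np.abs(res) / d_hat) < tol:
                break
            step = res if prev_res is None else np.where(res * prev_res < 0, 0.5 * res, res)
            d_hat = d_hat + step
            prev_res = res
        else:
            raise ConvergenceError(
                f"fixed point did not converge within {max_iter} iterations "
                f"(last relative residual {np.max(np.abs(res) / d_hat):.3e})",
                residual=float(np.max(np.abs(res))),
            )
    else:
        raise ValueError("model must be 'NBM' or 'BM'")

    rfp = consts.a * s_max[-1] / (d_hat * (mu + consts.a))
    gfp = None
    if topo.has_monitor and params.burden is not None:
        gfp = consts.a_G * params.burden.s_m / (d_hat * (mu + consts.a_G))
    return {"RFP": rfp, "GFP": gfp, "D_hat": d_hat}


def _result_from_chain(topo, cond, params, model, d_hat):
    consts = params.constants
    s_max, protein = _chain(topo, cond.hsl, cond.mu, params, d_hat)
    s = [sm / d_hat for sm in s_max]
    R = s[-1] / (cond.mu + consts.a)
    res = SteadyStateResult(
        circuit_id=topo.circuit_id,
        model=model,
        d_hat=float(d_hat),
        s_max=[float(v) for v in s_max],
        s=[float(v) for v in s],
        protein=[float(v) for v in protein],
        R=float(R),
        s_cell_norm_rfp=float(consts.a * R),
    )
    if topo.has_monitor and params.burden is not None:
        G = params.burden.s_m / (d_hat * (cond.mu + consts.a_G))
        res.G = float(G)
        res.s_cell_norm_gfp = float(consts.a_G * G)
    return res


def nbm_steady_state(
    topo: CircuitTopology, cond: Condition, params: CascadeParameters
) -> SteadyStateResult:
    """Explicit no-burden steady state (D_hat = 1)."""
    return _result_from_chain(topo, cond, params, "NBM", 1.0)


def bm_steady_state(
    topo: CircuitTopology,
    cond: Condition,
    params: CascadeParameters,
    tol: float = 1e-9,
    max_iter: int = 10_000,
) -> SteadyStateResult:
    """Self-consistent burden-model steady state via damped fixed point."""
    out = cascade_outputs(topo, [cond.hsl], [cond.mu], params, "BM", tol=tol, max_iter=max_iter)
    return _result_from_chain(topo, cond, params, "BM", float(out["D_hat"][0]))


def ode_reference_steady_state(
    topo: CircuitTopology,
    cond: Condition,
    params: CascadeParameters,
    model: str = "NBM",
    t_end: float = 100_000.0,
    rtol: float = 1e-9,
) -> SteadyStateResult:
    """Independent oracle: integrate the cascade kinetics to quasi-steady state.

    State variables are the gate repressor levels, the immature reporter and
    (if present) the immature monitor GFP; under the BM the shared capacity
    denominator is recomputed from the instantaneous protein levels at every
    step.
    """
    consts = params.constants
    n_gates = len(topo.gates)
    gammas = [getattr(consts, GATE_INFO[g][0]) for g in topo.gates]
    has_gfp = topo.has_monitor and params.burden is not None
    if model == "BM":
        if params.burden is None:
            raise ValueError("BM integration requires burden parameters")
        sigma = params.burden.sigma.get(topo.sigma_class, 0.0)
        loads = _gene_loads(topo, params)

    def rhs(_t, y):
        p = y[:n_gates]
        rate = (
            0.0
            if topo.input_device == "none"
            else hill_rate(params.hill[topo.input_device], cond.hsl)
        )
        s_max = [rate]
        for i, gate in enumerate(topo.gates):
            rate = hill_rate(params.hill[gate], max(p[i], 0.0))
            s_max.append(rate)
        if model == "BM":
            d = 1.0 + sigma + sum(J * s for J, s in zip(loads, s_max))
        else:
            d = 1.0
        dy = np.empty_like(y)
        for i in range(n_gates):
            dy[i] = s_max[i] / d - (cond.mu + gammas[i]) * p[i]
        dy[n_gates] = s_max[-1] / d - (cond.mu + consts.a) * y[n_gates]
        if has_gfp:
            dy[n_gates + 1] = params.burden.s_m / d - (cond.mu + consts.a_G) * y[n_gates + 1]
        return dy

    y0 = np.zeros(n_gates + 1 + int(has_gfp))
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="LSODA", rtol=rtol, atol=1e-12)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    yf = sol.y[:, -1]

    # reconstruct the denominator and rates from the final state
    rate = (
        0.0 if topo.input_device == "none" else hill_rate(params.hill[topo.input_device], cond.hsl)
    )
    s_max = [rate]
    for i, gate in enumerate(topo.gates):
        s_max.append(hill_rate(params.hill[gate], max(yf[i], 0.0)))
    d = 1.0
    if model == "BM":
        d = 1.0 + sigma + sum(J * s for J, s in zip(loads, s_max))
    R = float(yf[n_gates])
    res = SteadyStateResult(
        circuit_id=topo.circuit_id,
        model=model,
        d_hat=float(d),
        s_max=[float(v) for v in s_max],
        s=[float(v / d) for v in s_max],
        protein=[float(v) for v in yf[:n_gates]],
        R=R,
        s_cell_norm_rfp=float(consts.a * R),
    )
    if has_gfp:
        res.G = float(yf[n_gates + 1])
        res.s_cell_norm_gfp = float(consts.a_G * res.G)
    return res


@dataclass
class LogicClassification:
    label: str  # "OFF-to-ON" | "ON-to-OFF" | "flat"
    expected: str | None = None
    mismatch: bool | None = None
    median_at_zero: float = field(default=np.nan)
    median_at_max: float = field(default=np.nan)


def classify_logic_behaviour(
    outputs_at_zero,
    outputs_at_max,
    expected_direction: int | None = None,
    rel_tol: float = 0.05,
) -> LogicClassification:
    """Classify a circuit's logic from its output at zero vs maximal HSL.

    The two arguments are value distributions (replicates or Monte Carlo
    draws); central values are compared, and a relative difference below
    ``rel_tol`` is called flat.  ``expected_direction`` (+1 rising / -1
    falling, e.g. ``topology.expected_direction`` from the parity of
    repressible elements) yields a mismatch flag for circuits whose observed
    switching contradicts their composed logic.
    """
    lo = np.asarray(outputs_at_zero, dtype=float)
    hi = np.asarray(outputs_at_max, dtype=float)
    if lo.size == 0 or hi.size == 0:
        raise ValueError("both distributions must be non-empty")
    med_lo, med_hi = float(np.median(lo)), float(np.median(hi))
    if lo.std() == 0 and hi.std() == 0 and med_lo == med_hi:
        warnings.warn("identical zero-spread distributions; classifying as flat", stacklevel=2)
        label = "flat"
    elif abs(med_hi - med_lo) <= rel_tol * max(abs(med_lo), abs(med_hi), 1e-300):
        label = "flat"
    elif med_hi > med_lo:
        label = "OFF-to-ON"
    else:
        label = "ON-to-OFF"

    expected = None
    mismatch = None
    if expected_direction is not None:
        expected = "OFF-to-ON" if expected_direction > 0 else "ON-to-OFF"
        mismatch = label != expected
    return LogicClassification(
        label=label,
        expected=expected,
        mismatch=mismatch,
        median_at_zero=med_lo,
        median_at_max=med_hi,
    )
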