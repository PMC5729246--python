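"""Synthetic dose-response datasets and raw plate kinetics.

The in vivo measurements behind the cascade collection are not deposited, so
this module generates data with the statistical structure the analysis
assumes: steady-state model outputs per circuit x HSL, replicate Gaussian
noise truncated at zero, circuit- and HSL-specific growth rates, and - one
level rawer - full microplate kinetic exports (OD600, red and green
fluorescence with instrument backgrounds and OD-dependent green
autofluorescence) that the plate-processing module can reduce back.

Defaults mirror the study conditions: a 9-point HSL grid (0 plus 8
log-spaced points from 0.1 nM to 10 uM), 3 biological replicates, 10 %
replicate CV, and growth rates declining with the circuit's burden proxy
over roughly a 2.5-fold range (0.02 down to 0.008 min^-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import circuits as circuits_mod
from .datasets import DoseResponseDataset
from .params import CascadeParameters, default_parameters, with_weak_tet
from .plate import PlateWellSeries
from .steady_state import cascade_outputs

DEFAULT_CV = 0.10
DEFAULT_N_REPLICATES = 3
MU_RANGE = (0.008, 0.02)  # min^-1, spanning the strains' 2.5-fold range


def default_hsl_grid() -> np.ndarray:
    """0 plus 8 log-spaced HSL concentrations from 0.1 nM to 10 uM."""
    return np.concatenate([[0.0], np.geomspace(0.1, 1e4, 8)])


def default_growth_rates(
    topologies: list[circuits_mod.CircuitTopology],
    hsl_grid: np.ndarray | None = None,
    params: CascadeParameters | None = None,
    mu_range: tuple[float, float] = MU_RANGE,
) -> pd.DataFrame:
    """Growth-rate table mu(circuit, HSL) declining linearly with burden.

    The burden proxy is the resource denominator excess (D_hat - 1) of the
    burden model evaluated at the packaged training-set parameters and a
    mid-range growth rate; the proxy is normalised over the whole collection
    and mapped linearly onto ``mu_range`` (heaviest burden -> slowest
    growth).  Deterministic and configurable; a stand-in for the measured
    per-strain growth rates, which are figure-only in the source study.
    """
    if hsl_grid is None:
        hsl_grid = default_hsl_grid()
    if params is None:
        params = with_weak_tet(default_parameters("BM_training"))
    hsl_grid = np.asarray(hsl_grid, dtype=float)
    mu_probe = float(np.mean(mu_range))
    proxies = {}
    for topo in topologies:
        out = cascade_outputs(topo, hsl_grid, np.full_like(hsl_grid, mu_probe), params, "BM")
        proxies[topo.circuit_id] = out["D_hat"] - 1.0
    pmax = max(float(np.max(v)) for v in proxies.values())
    pmax = pmax if pmax > 0 else 1.0
    rows = []
    for topo in topologies:
        mu = mu_range[1] - (mu_range[1] - mu_range[0]) * proxies[topo.circuit_id] / pmax
        for h, m in zip(hsl_grid, mu):
            rows.append(dict(circuit_id=topo.circuit_id, hsl_nM=float(h), mu=float(m)))
    return pd.DataFrame(rows)


def growth_rate_lookup(table: pd.DataFrame) -> dict[tuple[str, float], float]:
    return {
        (r["circuit_id"], float(r["hsl_nM"])): float(r["mu"]) for _, r in table.iterrows()
    }


@dataclass
class GenerationSpec:
    """Recipe for a synthetic dose-response dataset.

    ``model`` selects the generating steady-state model; ``truth_column``
    the packaged parameter column used as ground truth (overridden by
    ``overrides``, flat dotted keys).  Noise is per-condition Gaussian with
    relative ``cv`` (or absolute ``sigma_abs`` if set); negatives are
    truncated at zero.  ``seed`` is mandatory.
    """

    seed: int
    model: str = "NBM"
    truth_column: str = "NBM_training"
    circuits: list[str] = field(default_factory=lambda: circuits_mod.training_ids())
    hsl_grid: list[float] = field(default_factory=lambda: default_hsl_grid().tolist())
    n_replicates: int = DEFAULT_N_REPLICATES
    cv: float = DEFAULT_CV
    sigma_abs: float | None = None
    overrides: dict[str, float] = field(default_factory=dict)
    growth_rates: dict[tuple[str, float], float] | None = None

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.model not in ("NBM", "BM"):
            raise ValueError("model must be 'NBM' or 'BM'")

    def parameters(self) -> CascadeParameters:
        params = with_weak_tet(default_parameters(self.truth_column))
        if self.overrides:
            params = params.updated(self.overrides)
        return params

    # YAML round-trip (growth-rate tables serialise as nested dicts)
    def to_yaml(self, path) -> None:
        payload = {
            "seed": self.seed,
            "model": self.model,
            "truth_column": self.truth_column,
            "circuits": list(self.circuits),
            "hsl_grid": [float(h) for h in self.hsl_grid],
            "n_replicates": self.n_replicates,
            "cv": self.cv,
            "sigma_abs": self.sigma_abs,
            "overrides": dict(self.overrides),
            "growth_rates": (
                None
                if self.growth_rates is None
                else [
                    {"circuit_id": c, "hsl_nM": h, "mu": m}
                    for (c, h), m in sorted(self.growth_rates.items())
                ]
            ),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GenerationSpec":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        gr = payload.pop("growth_rates", None)
        spec = cls(**payload)
        if gr is not None:
            spec.growth_rates = {(r["circuit_id"], float(r["hsl_nM"])): float(r["mu"]) for r in gr}
        return spec


def generate_dose_response(spec: GenerationSpec) -> DoseResponseDataset:
    """Evaluate the chosen model on the grid and add truncated replicate noise.

    GFP rows are emitted for monitor-bearing circuits whenever the parameter
    set carries burden terms (the monitor rate S_m lives there).
    """
    params = spec.parameters()
    if spec.model == "BM" and params.burden is None:
        raise ValueError(f"BM generation requires burden parameters ({spec.truth_column})")
    reg = circuits_mod.registry()
    hsl = np.asarray(spec.hsl_grid, dtype=float)
    if spec.growth_rates is None:
        topologies = [reg[c] for c in spec.circuits]
        mu_lookup = growth_rate_lookup(default_growth_rates(topologies, hsl))
    else:
        mu_lookup = spec.growth_rates
    rng = np.random.default_rng(spec.seed)

    rows = []
    for cid in spec.circuits:
        topo = reg[cid]
        mu = np.array([mu_lookup[(cid, float(h))] for h in hsl])
        out = cascade_outputs(topo, hsl, mu, params, spec.model)
        observables = {"RFP": out["RFP"]}
        if out["GFP"] is not None:
            observables["GFP"] = out["GFP"]
        for obs, truth in observables.items():
            sd = spec.sigma_abs if spec.sigma_abs is not None else spec.cv * np.abs(truth)
            noise = rng.normal(0.0, 1.0, size=(spec.n_replicates, len(hsl))) * sd
            values = np.clip(truth[None, :] + noise, 0.0, None)
            for rep in range(spec.n_replicates):
                for k, h in enumerate(hsl):
                    rows.append(
                        dict(
                            circuit_id=cid,
                            hsl_nM=float(h),
                            replicate=rep + 1,
                            observable=obs,
                            value=float(values[rep, k]),
                            mu=float(mu[k]),
                        )
                    )
    return DoseResponseDataset(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# raw plate kinetics


def _od_curve(t, mu, lag, od0, od_max, law):
    tau = np.clip(t - lag, 0.0, None)
    if law == "exp_cap":
        return np.minimum(od0 * np.exp(mu * tau), od_max)
    if law == "logistic":
        e = od0 * np.exp(mu * tau)
        return od_max * e / (od_max - od0 + e)
    raise ValueError("growth law must be 'exp_cap' or 'logistic'")


def _fluo_curve(t, od, s):
    """Accumulated fluorescence dF/dt = s * OD, integrated on the grid."""
    f = np.zeros_like(t)
    f[1:] = np.cumsum(0.5 * (od[1:] + od[:-1]) * np.diff(t)) * s
    return f


def generate_plate_kinetics(
    mu: float,
    s_rfp: float,
    s_gfp: float | None = None,
    *,
    circuit_id: str = "synthetic",
    hsl: float = 0.0,
    n_replicates: int = 3,
    lag: float = 60.0,
    od0: float = 0.02,
    od_max: float = 0.6,
    duration: float = 900.0,
    dt: float = 5.0,
    growth_law: str = "exp_cap",
    autofluo_q: float = 3.0,
    autofluo_m: float = 8.0,
    abs_background: float = 0.04,
    red_background: float = 120.0,
    green_background: float = 0.0,
    reference_rates: tuple[float, float] = (500.0, 500.0),
    reference_mu: float = 0.02,
    noise_od: float = 5e-4,
    noise_fluo: float = 0.5,
    seed: int = 0,
) -> list[PlateWellSeries]:
    """Emulate one microplate run for a single culture condition.

    Growth starts at ``od0`` after a lag and is exponential at rate ``mu``
    until saturation at ``od_max`` (a logistic law is available; the
    exponential-window reduction only ever sees the pre-saturation phase).
    Fluorescence accumulates as dF/dt = s * OD with ``s`` the effective
    per-cell synthesis rate per channel (maturation folded in); the green
    channel additionally carries the cell-density autofluorescence
    exp(q + m*OD) and every channel a constant instrument background.
    Matched blanks, no-GFP autofluorescence controls and constitutive
    reference wells (rates ``reference_rates``) are emitted alongside the
    samples.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    if od_max <= 0.18:
        raise ValueError("od_max must exceed 0.18 so the exponential window is traversed")
    t = np.arange(0.0, duration + dt / 2, dt)
    od_probe = _od_curve(t, mu, lag, od0, od_max, growth_law)
    if od_probe.max() < 0.18:
        raise ValueError("window never traversed: extend duration or raise mu")
    rng = np.random.default_rng(seed)

    def culture_well(well, role, s_r, s_g, mu_c, with_gfp_cassette, cid, rep):
        od = _od_curve(t, mu_c, lag, od0, od_max, growth_law)
        absorbance = od + abs_background + rng.normal(0, noise_od, t.shape)
        red = _fluo_curve(t, od, s_r) + red_background + rng.normal(0, noise_fluo, t.shape)
        green = np.exp(autofluo_q + autofluo_m * od) + green_background
        if with_gfp_cassette:
            green = green + _fluo_curve(t, od, s_g)
        green = green + rng.normal(0, noise_fluo, t.shape)
        return PlateWellSeries(
            well=well,
            role=role,
            time=t.copy(),
            absorbance=absorbance,
            red=red,
            green=green,
            circuit_id=cid,
            hsl=hsl,
            replicate=rep,
        )

    wells: list[PlateWellSeries] = []
    has_gfp = s_gfp is not None
    for rep in range(1, n_replicates + 1):
        wells.append(
            culture_well(
                f"S{rep}", "sample", s_rfp, s_gfp if has_gfp else 0.0, mu, has_gfp,
                circuit_id, rep,
            )
        )
    for rep in (1, 2):  # no-GFP strain, matched circuit and HSL
        wells.append(culture_well(f"C{rep}", "autofluo_control", s_rfp, 0.0, mu, False,
                                  circuit_id, rep))
    for rep in (1, 2):  # sterile medium
        wells.append(
            PlateWellSeries(
                well=f"B{rep}",
                role="abs_blank",
                time=t.copy(),
                absorbance=abs_background + rng.normal(0, noise_od, t.shape),
                red=np.full_like(t, red_background),
                green=np.full_like(t, green_background),
                replicate=rep,
            )
        )
    for rep in (1, 2):  # non-fluorescent culture for the red background
        wells.append(
            PlateWellSeries(
                well=f"R{rep}",
                role="red_blank",
                time=t.copy(),
                absorbance=_od_curve(t, mu, lag, od0, od_max, growth_law) + abs_background,
                red=red_background + rng.normal(0, noise_fluo, t.shape),
                replicate=rep,
            )
        )
    for rep in (1, 2, 3):
        wells.append(
            culture_well(f"RR{rep}", "reference_RFP", reference_rates[0], 0.0, reference_mu,
                         False, "reference", rep)
        )
        wells.append(
            culture_well(f"RG{rep}", "reference_GFP", 0.0, reference_rates[1], reference_mu,
                         True, "reference", rep)
        )
    return wells


def plate_wells_from_dose_response(
    dataset: DoseResponseDataset,
    reference_rates: tuple[float, float] = (500.0, 500.0),
    seed: int = 0,
    **kinetics_kwargs,
) -> list[PlateWellSeries]:
    """Forward-generate plate kinetics whose reduction reproduces a
    dose-response table (normalised rates mapped through the reference
    rates).  One shared set of blanks and references; per-condition samples
    and autofluorescence controls."""
    means = dataset.condition_means().pivot_table(
        index=["circuit_id", "hsl_nM"], columns="observable", values="value"
    )
    mu_table = dataset.mu_table().set_index(["circuit_id", "hsl_nM"])["mu"]
    wells: list[PlateWellSeries] = []
    first = True
    for i, (key, row) in enumerate(means.iterrows()):
        cid, h = key
        s_rfp = float(row["RFP"]) * reference_rates[0]
        s_gfp = float(row["GFP"]) * reference_rates[1] if "GFP" in row and np.isfinite(
            row.get("GFP", np.nan)
        ) else None
        group = generate_plate_kinetics(
            mu=float(mu_table.loc[key]),
            s_rfp=s_rfp,
            s_gfp=s_gfp,
            circuit_id=cid,
            hsl=float(h),
            reference_rates=reference_rates,
            seed=seed + i,
            **kinetics_kwargs,
        )
        for w in group:
            if w.role in ("abs_blank", "red_blank", "reference_RFP", "reference_GFP"):
                if not first:
                    continue
            w.well = f"{cid}@{h:g}:{w.well}" if w.role in ("sample", "autofluo_control") else w.well
            wells.append(w)
        first = False
    return wells
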