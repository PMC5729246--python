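"""Reduction of raw microplate kinetics to per-cell synthesis rates.

The measurement chain: raw absorbance and fluorescence time series are
blanked (medium for absorbance, a non-fluorescent culture for the red
channel, a fitted cell-density-dependent autofluorescence curve
``exp(q + m*OD600)`` for the green channel); the fluorescent-protein
synthesis rate per cell is ``S_cell = (dF/dt) / OD600`` averaged over the
exponential window ``0.05 <= OD600 <= 0.18``; the growth rate is the slope
of ``ln(OD600)`` vs time in the same window; and rates are normalised to the
mean ``S_cell`` of a channel-matched constitutive reference culture, giving
a relative-promoter-unit-like scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_WINDOW = (0.05, 0.18)
ROLES = (
    "sample",
    "abs_blank",
    "red_blank",
    "autofluo_control",
    "reference_RFP",
    "reference_GFP",
    "monitor_only",
)


@dataclass
class PlateWellSeries:
    """Raw kinetic series of one well with plate-map metadata."""

    well: str
    role: str
    time: np.ndarray  # min
    absorbance: np.ndarray
    red: np.ndarray
    green: np.ndarray | None = None
    circuit_id: str = ""
    hsl: float = 0.0
    replicate: int = 1

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        self.red = np.asarray(self.red, dtype=float)
        if self.green is not None:
            self.green = np.asarray(self.green, dtype=float)
        lengths = {len(self.time), len(self.absorbance), len(self.red)}
        if self.green is not None:
            lengths.add(len(self.green))
        if len(lengths) != 1:
            raise ValueError(f"well {self.well}: series lengths differ")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError(f"well {self.well}: time must be strictly increasing")
        if self.role not in ROLES:
            raise ValueError(f"well {self.well}: unknown role {self.role!r}")


@dataclass
class AutofluorescenceModel:
    """OD-dependent green background, GFP_auto = exp(q + m * OD600)."""

    q: float
    m: float

    def predict(self, od) -> np.ndarray:
        return np.exp(self.q + self.m * np.asarray(od, dtype=float))


@dataclass
class BlankedSeries:
    time: np.ndarray
    od: np.ndarray
    rfp: np.ndarray
    gfp: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)


def _mean_series(wells: list[PlateWellSeries], channel: str, like: PlateWellSeries) -> np.ndarray:
    if not wells:
        raise ValueError(f"no blank wells supplied for channel {channel}")
    arrays = []
    for w in wells:
        if len(w.time) != len(like.time) or not np.allclose(w.time, like.time):
            raise ValueError(f"blank well {w.well} is not time-aligned with {like.well}")
        arrays.append(getattr(w, channel))
    return np.mean(arrays, axis=0)


def blank_series(
    sample: PlateWellSeries,
    abs_blanks: list[PlateWellSeries],
    red_blanks: list[PlateWellSeries],
    autofluo: AutofluorescenceModel | None = None,
    od_tolerance: float = 0.01,
) -> BlankedSeries:
    """Background-subtract one well.

    Absorbance is blanked with the sterile-medium wells, the red channel with
    a non-fluorescent culture, and the green channel (when present) with the
    OD-evaluated autofluorescence model, which is therefore required.
    """
    od = sample.absorbance - _mean_series(abs_blanks, "absorbance", sample)
    rfp = sample.red - _mean_series(red_blanks, "red", sample)
    flags = []
    if np.min(od) < -od_tolerance:
        flags.append("negative_od")
    gfp = None
    if sample.green is not None:
        if autofluo is None:
            raise ValueError(
                f"well {sample.well}: green channel present but no autofluorescence model"
            )
        gfp = sample.green - autofluo.predict(od)
    return BlankedSeries(time=sample.time, od=od, rfp=rfp, gfp=gfp, flags=flags)


def fit_autofluorescence(
    controls: list[PlateWellSeries],
    abs_blanks: list[PlateWellSeries],
) -> AutofluorescenceModel:
    """Fit ln(green) vs blanked OD600 on pooled no-GFP control wells.

    Equivalent to the exponential regression GFP_auto = exp(q + m*OD).
    Non-positive green readings are dropped (log undefined) with a warning.
    """
    if len(controls) < 2:
        warnings.warn(
            f"autofluorescence fit on {len(controls)} control replicate(s); >= 2 recommended",
            stacklevel=2,
        )
    od_all, green_all = [], []
    for w in controls:
        od = w.absorbance - _mean_series(abs_blanks, "absorbance", w)
        if w.green is None:
            raise ValueError(f"control well {w.well} has no green channel")
        od_all.append(od)
        green_all.append(w.green)
    od = np.concatenate(od_all)
    green = np.concatenate(green_all)
    usable = green > 0
    if np.any(~usable):
        warnings.warn(
            f"excluding {int((~usable).sum())} non-positive green reading(s) from "
            "autofluorescence fit",
            stacklevel=2,
        )
    od, green = od[usable], green[usable]
    if len(od) < 3:
        raise ValueError("fewer than 3 usable points for autofluorescence fit")
    if np.ptp(od) == 0:  # flat OD: model degenerates to a constant
        return AutofluorescenceModel(q=float(np.mean(np.log(green))), m=0.0)
    m, q = np.polyfit(od, np.log(green), 1)
    return AutofluorescenceModel(q=float(q), m=float(m))


def _window_mask(od: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    # closed interval: boundary points included
    return (od >= window[0]) & (od <= window[1])


def compute_growth_rate(
    time: np.ndarray, od: np.ndarray, window: tuple[float, float] = DEFAULT_WINDOW
) -> float:
    """Slope of ln(OD600) vs time (min^-1) inside the exponential window."""
    time = np.asarray(time, dtype=float)
    od = np.asarray(od, dtype=float)
    mask = _window_mask(od, window) & (od > 0)
    if mask.sum() < 3:
        raise ValueError(
            f"fewer than 3 points with OD in [{window[0]}, {window[1]}] "
            f"(observed OD range {od.min():.3g}..{od.max():.3g})"
        )
    fit = stats.linregress(time[mask], np.log(od[mask]))
    return float(fit.slope)


def compute_synthesis_rate(
    time: np.ndarray,
    fluo: np.ndarray,
    od: np.ndarray,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> float:
    """Mean of (dF/dt)/OD600 over the exponential window.

    The derivative uses centred finite differences on the sampling grid
    (one-sided at the endpoints).
    """
    time = np.asarray(time, dtype=float)
    fluo = np.asarray(fluo, dtype=float)
    od = np.asarray(od, dtype=float)
    mask = _window_mask(od, window) & (od > 0)
    if mask.sum() < 2:
        raise ValueError(
            f"fewer than 2 points with OD in [{window[0]}, {window[1]}] "
            f"(observed OD range {od.min():.3g}..{od.max():.3g})"
        )
    dfdt = np.gradient(fluo, time)
    return float(np.mean(dfdt[mask] / od[mask]))


def normalize_to_reference(s_cell_target, s_cell_reference_replicates) -> float | np.ndarray:
    """Divide by the mean reference-culture S_cell (channel-matched)."""
    ref = np.asarray(s_cell_reference_replicates, dtype=float)
    if ref.size == 0:
        raise ValueError("no reference replicates supplied")
    mean_ref = float(np.mean(ref))
    if mean_ref <= 0:
        raise ValueError(f"non-positive mean reference S_cell ({mean_ref:.3g})")
    out = np.asarray(s_cell_target, dtype=float) / mean_ref
    return float(out) if out.ndim == 0 else out


def correlation_analysis(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations with two-sided p-values.

    Constant columns yield NaN entries (correlation undefined).
    """
    cols = list(table.columns)
    if len(table) < 3:
        raise ValueError("need at least 3 paired observations")
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, ci in enumerate(cols):
        for j, cj in enumerate(cols):
            if j <= i:
                continue
            x, y = table[ci].to_numpy(float), table[cj].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                rij, pij = np.nan, np.nan
            else:
                rij, pij = stats.pearsonr(x[ok], y[ok])
            r.loc[ci, cj] = r.loc[cj, ci] = rij
            p.loc[ci, cj] = p.loc[cj, ci] = pij
    return r, p


# ---------------------------------------------------------------------------
# whole-plate reduction


def process_plate(
    wells: list[PlateWellSeries],
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Reduce a full plate to per-culture summaries.

    Autofluorescence models are fitted per (circuit, HSL) matched control
    group, falling back to a pooled model; reference wells provide the
    channel-matched normalisation denominators.  Returns one row per culture
    well with growth rate, S_cell and normalised S_cell per channel.
    """
    abs_blanks = [w for w in wells if w.role == "abs_blank"]
    red_blanks = [w for w in wells if w.role == "red_blank"]
    controls = [w for w in wells if w.role == "autofluo_control"]
    if not abs_blanks or not red_blanks:
        raise ValueError("plate must contain abs_blank and red_blank wells")

    autofluo_by_key: dict[tuple[str, float], AutofluorescenceModel] = {}
    for key in {(w.circuit_id, w.hsl) for w in controls}:
        group = [w for w in controls if (w.circuit_id, w.hsl) == key]
        autofluo_by_key[key] = fit_autofluorescence(group, abs_blanks)
    pooled = fit_autofluorescence(controls, abs_blanks) if controls else None

    def reduce_well(w: PlateWellSeries) -> dict:
        model = autofluo_by_key.get((w.circuit_id, w.hsl), pooled) if w.green is not None else None
        blanked = blank_series(w, abs_blanks, red_blanks, autofluo=model)
        mu = compute_growth_rate(blanked.time, blanked.od, window)
        row = {
            "well": w.well,
            "role": w.role,
            "circuit_id": w.circuit_id,
            "hsl_nM": w.hsl,
            "replicate": w.replicate,
            "mu": mu,
            "s_cell_rfp": compute_synthesis_rate(blanked.time, blanked.rfp, blanked.od, window),
            "s_cell_gfp": (
                compute_synthesis_rate(blanked.time, blanked.gfp, blanked.od, window)
                if blanked.gfp is not None
                else np.nan
            ),
            "flags": ";".join(blanked.flags),
        }
        return row

    measured_roles = ("sample", "monitor_only", "reference_RFP", "reference_GFP")
    rows = [reduce_well(w) for w in wells if w.role in measured_roles]
    out = pd.DataFrame(rows)

    ref_rfp = out.loc[out["role"] == "reference_RFP", "s_cell_rfp"].to_numpy()
    ref_gfp = out.loc[out["role"] == "reference_GFP", "s_cell_gfp"].to_numpy()
    out["s_norm_rfp"] = (
        normalize_to_reference(out["s_cell_rfp"].to_numpy(), ref_rfp) if ref_rfp.size else np.nan
    )
    out["s_norm_gfp"] = (
        normalize_to_reference(out["s_cell_gfp"].to_numpy(), ref_gfp)
        if ref_gfp.size and np.isfinite(ref_gfp).all()
        else np.nan
    )
    return out


def dose_response_from_summaries(summaries: pd.DataFrame) -> pd.DataFrame:
    """Tidy long-format rows (circuit_id, hsl_nM, replicate, observable, value, mu)
    from per-culture summaries, for hand-off to the inference module."""
    rows = []
    samples = summaries[summaries["role"].isin(["sample", "monitor_only"])]
    for _, r in samples.iterrows():
        rows.append(
            dict(
                circuit_id=r["circuit_id"],
                hsl_nM=r["hsl_nM"],
                replicate=r["replicate"],
                observable="RFP",
                value=max(r["s_norm_rfp"], 0.0),
                mu=r["mu"],
            )
        )
        if np.isfinite(r["s_norm_gfp"]):
            rows.append(
                dict(
                    circuit_id=r["circuit_id"],
                    hsl_nM=r["hsl_nM"],
                    replicate=r["replicate"],
                    observable="GFP",
                    value=max(r["s_norm_gfp"], 0.0),
                    mu=r["mu"],
                )
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plate CSV dialect: long-format export plus plate map


def write_plate_csv(wells: list[PlateWellSeries], data_path, map_path) -> None:
    data_rows, map_rows = [], []
    for w in wells:
        map_rows.append(
            dict(
                well=w.well,
                role=w.role,
                circuit_id=w.circuit_id,
                hsl_nM=w.hsl,
                replicate=w.replicate,
            )
        )
        channels = {"absorbance_600": w.absorbance, "red": w.red}
        if w.green is not None:
            channels["green"] = w.green
        for channel, values in channels.items():
            for t, v in zip(w.time, values):
                data_rows.append(dict(well=w.well, time_min=t, channel=channel, value=v))
    pd.DataFrame(data_rows).to_csv(data_path, index=False)
    pd.DataFrame(map_rows).to_csv(map_path, index=False)


def read_plate_csv(data_path, map_path) -> list[PlateWellSeries]:
    data = pd.read_csv(data_path)
    plate_map = pd.read_csv(map_path).set_index("well")
    wells = []
    for well, group in data.groupby("well", sort=False):
        meta = plate_map.loc[well]
        wide = group.pivot_table(index="time_min", columns="channel", values="value").sort_index()
        wells.append(
            PlateWellSeries(
                well=str(well),
                role=str(meta["role"]),
                time=wide.index.to_numpy(),
                absorbance=wide["absorbance_600"].to_numpy(),
                red=wide["red"].to_numpy(),
                green=wide["green"].to_numpy() if "green" in wide.columns else None,
                circuit_id=str(meta["circuit_id"]),
                hsl=float(meta["hsl_nM"]),
                replicate=int(meta["replicate"]),
            )
        )
    return wells
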