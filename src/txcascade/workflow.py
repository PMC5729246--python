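"""Configuration-driven orchestration of the full cascade analysis.

Stages (in fixed order): ``simulate`` (synthetic dose-response collection,
optionally raw plate kinetics), ``process`` (plate reduction), ``fit``
(bottom-up training fits with bootstrap distributions for both models),
``predict`` (test-set Monte Carlo bands and performance correlations),
``sensitivity``, ``compare`` (simultaneous fits and likelihood-ratio test)
and ``report``.  Every stage writes its outputs before the next starts and
derives its seed deterministically from the master seed, so a fixed
configuration reproduces byte-identical summaries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import circuits as circuits_mod
from .datasets import DoseResponseDataset
from .fitting import (
    bootstrap_training_bm,
    bootstrap_training_nbm,
    fit_simultaneous,
    lr_test,
)
from .params import CascadeParameters
from .plate import dose_response_from_summaries, process_plate, read_plate_csv, write_plate_csv
from .predict import (
    ParameterDistribution,
    SensitivitySpec,
    predict_circuit,
    prediction_performance,
    sensitivity_univariate,
)
from .simulate import (
    GenerationSpec,
    default_hsl_grid,
    generate_dose_response,
    plate_wells_from_dose_response,
)
from .steady_state import classify_logic_behaviour

logger = logging.getLogger(__name__)

STAGE_ORDER = ["simulate", "process", "fit", "predict", "sensitivity", "compare", "report"]


class WorkflowConfigError(ValueError):
    pass


@dataclass
class WorkflowConfig:
    """Validated workflow settings; round-trips losslessly through YAML."""

    out_dir: str
    master_seed: int | None = None
    name: str = "workflow"
    stages: list[str] = field(default_factory=lambda: ["simulate", "fit", "predict", "report"])
    truth_model: str = "BM"
    truth_column: str = "BM_training"
    hsl_grid: list[float] | None = None
    n_replicates: int = 3
    cv: float = 0.10
    include_plate: bool = False
    n_bootstrap_nbm: int = 100
    n_bootstrap_bm: int = 20
    n_prediction_draws: int = 100
    sensitivity_cv: float = 0.25
    sensitivity_target: str = "delta"
    sensitivity_circuits: list[str] = field(default_factory=lambda: ["X_rep_Tr"])

    def validate(self) -> None:
        errors = []
        if self.master_seed is None:
            errors.append("master_seed: required (no silent default)")
        unknown = [s for s in self.stages if s not in STAGE_ORDER]
        if unknown:
            errors.append(f"stages: unknown stage(s) {unknown}")
        if self.cv < 0:
            errors.append("cv: must be >= 0")
        if self.truth_model not in ("NBM", "BM"):
            errors.append("truth_model: must be NBM or BM")
        if self.n_replicates < 1:
            errors.append("n_replicates: must be >= 1")
        if "process" in self.stages and not self.include_plate:
            errors.append("process: requires include_plate=true (no plate data to reduce)")
        if errors:
            raise WorkflowConfigError("invalid workflow config:\n  " + "\n  ".join(errors))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "WorkflowConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        known = {f for f in cls.__dataclass_fields__}
        extra = set(payload) - known
        if extra:
            raise WorkflowConfigError(f"invalid workflow config:\n  unknown field(s) {sorted(extra)}")
        return cls(**payload)

    @classmethod
    def packaged_default(cls) -> "WorkflowConfig":
        with resources.files("txcascade.data").joinpath("config_default.yaml").open() as fh:
            return cls(**yaml.safe_load(fh))


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds (< 2^31) derived from the master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(len(STAGE_ORDER))
    return {name: int(s & 0x7FFFFFFF) for name, s in zip(STAGE_ORDER, state)}


def _params_table(flat: dict[str, float], cv: pd.Series | None) -> pd.DataFrame:
    rows = []
    for name, value in sorted(flat.items()):
        cvpct = float(cv[name]) * 100 if cv is not None and name in cv and value > 0 else np.nan
        rows.append(dict(parameter=name, value=value, cv_percent=cvpct))
    return pd.DataFrame(rows)


def run_workflow(config: WorkflowConfig) -> dict:
    """Execute the configured stages in order; returns the summary dict.

    Outputs land under ``config.out_dir``; ``summary.json`` lists per-stage
    status, seeds and key estimates and is deterministic for a fixed config.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.master_seed)
    registry = circuits_mod.registry()
    hsl = np.asarray(config.hsl_grid if config.hsl_grid else default_hsl_grid(), float)

    summary: dict = {"name": config.name, "master_seed": config.master_seed, "stages": {}}
    stages = [s for s in STAGE_ORDER if s in config.stages]

    data: DoseResponseDataset | None = None
    fits: dict = {}
    try:
        for stage in stages:
            logger.info("stage %s (seed %d)", stage, seeds[stage])
            if stage == "simulate":
                circuits = circuits_mod.training_ids() + circuits_mod.test_ids()
                circuits += circuits_mod.training_ids(monitor=True) + circuits_mod.test_ids(
                    monitor=True
                )
                circuits.append("Mon_rg")  # monitor-only culture anchors S_m
                gen = GenerationSpec(
                    seed=seeds[stage],
                    model=config.truth_model,
                    truth_column=config.truth_column,
                    circuits=circuits,
                    hsl_grid=hsl.tolist(),
                    n_replicates=config.n_replicates,
                    cv=config.cv,
                )
                data = generate_dose_response(gen)
                data.to_csv(out / "dose_response.csv")
                gen.to_yaml(out / "generation_spec.yaml")
                summary["stages"][stage] = {
                    "status": "ok",
                    "seed": seeds[stage],
                    "n_rows": len(data),
                    "n_circuits": len(data.circuits),
                }
                if config.include_plate:
                    small = data.subset(circuits=circuits_mod.training_ids())
                    wells = plate_wells_from_dose_response(small, seed=seeds[stage])
                    write_plate_csv(wells, out / "plate_data.csv", out / "plate_map.csv")

            elif stage == "process":
                wells = read_plate_csv(out / "plate_data.csv", out / "plate_map.csv")
                summaries = process_plate(wells)
                summaries.to_csv(out / "plate_summaries.csv", index=False)
                tidy = dose_response_from_summaries(summaries)
                tidy.to_csv(out / "plate_dose_response.csv", index=False)
                summary["stages"][stage] = {
                    "status": "ok",
                    "seed": seeds[stage],
                    "n_wells": int(len(summaries)),
                }

            elif stage == "fit":
                if data is None:
                    data = DoseResponseDataset.from_csv(out / "dose_response.csv")
                point_nbm, dist_nbm = bootstrap_training_nbm(
                    data, n_datasets=config.n_bootstrap_nbm, seed=seeds[stage],
                    registry=registry,
                )
                if config.n_bootstrap_bm > 0:
                    point_bm, dist_bm = bootstrap_training_bm(
                        data, n_datasets=config.n_bootstrap_bm, seed=seeds[stage] + 1,
                        registry=registry,
                    )
                else:
                    from .fitting import fit_training_bm

                    point_bm = fit_training_bm(data, registry, seed=seeds[stage] + 1)
                    flat = {}
                    for f in point_bm.stage_fits.values():
                        flat.update(f.params_flat)
                    dist_bm = ParameterDistribution.from_point(flat)
                fits = {
                    "NBM": (point_nbm, dist_nbm),
                    "BM": (point_bm, dist_bm),
                }
                key_estimates = {}
                for model, (point, dist) in fits.items():
                    table = _params_table(
                        {k: float(v) for k, v in dist.median().items()}, dist.cv()
                    )
                    table.to_csv(out / f"params_{model.lower()}.csv", index=False)
                    dist.samples.to_csv(out / f"bootstrap_{model.lower()}.csv", index=False)
                    key_estimates[model] = {
                        k: round(float(v), 6) for k, v in sorted(dist.median().items())
                    }
                summary["stages"][stage] = {
                    "status": "ok",
                    "seed": seeds[stage],
                    "estimates": key_estimates,
                }

            elif stage == "predict":
                if data is None:
                    data = DoseResponseDataset.from_csv(out / "dose_response.csv")
                if not fits:
                    raise RuntimeError("predict stage requires the fit stage outputs")
                mu_table = data.mu_table()
                observed = data.condition_means()[
                    ["circuit_id", "hsl_nM", "observable", "value"]
                ]
                all_bands, perf_frames, logic_rows = [], [], []
                for model, (point, dist) in fits.items():
                    sample = dist.samples
                    if len(sample) > config.n_prediction_draws:
                        sample = sample.sample(
                            config.n_prediction_draws, random_state=seeds["predict"]
                        )
                    ids = circuits_mod.test_ids(monitor=(model == "BM"))
                    pred_rows = []
                    for cid in ids:
                        topo = registry[cid]
                        bands = predict_circuit(
                            topo, sample, point.params, mu_table, hsl, model=model
                        )
                        b = bands.bands.assign(circuit_id=cid, model=model)
                        all_bands.append(b)
                        pred_rows.append(
                            b.rename(columns={"median": "value"})[
                                ["circuit_id", "hsl_nM", "observable", "value"]
                            ]
                        )
                        rfp = bands.for_observable("RFP")
                        cls = classify_logic_behaviour(
                            [rfp["median"].iloc[0]],
                            [rfp["median"].iloc[-1]],
                            expected_direction=topo.expected_direction,
                            rel_tol=0.05,
                        )
                        logic_rows.append(
                            dict(model=model, circuit_id=cid, predicted=cls.label,
                                 expected=cls.expected, mismatch=cls.mismatch)
                        )
                    perf, _ = prediction_performance(observed, pd.concat(pred_rows))
                    perf_frames.append(perf.assign(model=model))
                pd.concat(all_bands).to_csv(out / "prediction_bands.csv", index=False)
                perf_all = pd.concat(perf_frames)
                perf_all.to_csv(out / "prediction_performance.csv", index=False)
                pd.DataFrame(logic_rows).to_csv(out / "logic_classification.csv", index=False)
                summary["stages"][stage] = {
                    "status": "ok",
                    "seed": seeds[stage],
                    "performance": [
                        {k: (round(v, 4) if isinstance(v, float) else v) for k, v in r.items()}
                        for r in perf_all.to_dict("records")
                    ],
                }

            elif stage == "sensitivity":
                if not fits:
                    raise RuntimeError("sensitivity stage requires the fit stage outputs")
                if data is None:
                    data = DoseResponseDataset.from_csv(out / "dose_response.csv")
                point, _dist = fits["NBM"]
                spec = SensitivitySpec(
                    mode="univariate", cv=config.sensitivity_cv, n_draws=500,
                    seed=seeds[stage],
                )
                frames = []
                for cid in config.sensitivity_circuits:
                    bands = sensitivity_univariate(
                        registry[cid], point.params, config.sensitivity_target, spec,
                        data.mu_table(), hsl, model="NBM",
                    )
                    frames.append(bands.bands.assign(circuit_id=cid))
                pd.concat(frames).to_csv(out / "sensitivity_bands.csv", index=False)
                summary["stages"][stage] = {"status": "ok", "seed": seeds[stage]}

            elif stage == "compare":
                if data is None:
                    data = DoseResponseDataset.from_csv(out / "dose_response.csv")
                init_nbm = fits["NBM"][0].params if fits else None
                init_bm = fits["BM"][0].params if fits else None
                plain = [c for c in data.circuits if not c.endswith("rg")]
                rfp_data = data.subset(circuits=plain, observables=["RFP"])
                fit_nbm = fit_simultaneous(
                    rfp_data, "NBM", registry, seed=seeds[stage], init_params=init_nbm
                )
                fit_bm = fit_simultaneous(
                    rfp_data, "BM", registry, seed=seeds[stage], init_params=init_bm
                )
                lr = lr_test(fit_nbm, fit_bm, observable="RFP")
                result = {
                    "ll_nbm": lr.ll_null,
                    "ll_bm": lr.ll_alt,
                    "statistic": lr.statistic,
                    "df": lr.df,
                    "pvalue": lr.pvalue,
                }
                with open(out / "model_comparison.json", "w") as fh:
                    json.dump(result, fh, indent=2)
                summary["stages"][stage] = {"status": "ok", "seed": seeds[stage], **result}

            elif stage == "report":
                report = write_report(out)
                summary["stages"][stage] = {"status": "ok", "path": report.name}
    except Exception as exc:  # partial outputs retained
        summary["stages"][stage] = {"status": "failed", "error": str(exc)}
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def write_report(out_dir) -> Path:
    """Render a human-readable markdown summary from whatever stage outputs
    are present in ``out_dir``; missing sections are noted."""
    out = Path(out_dir)
    sections = ["# Cascade analysis report\n"]
    found_any = False

    for model in ("nbm", "bm"):
        path = out / f"params_{model}.csv"
        if path.exists():
            found_any = True
            table = pd.read_csv(path)
            sections.append(f"## Estimated parameters ({model.upper()})\n")
            sections.append("| parameter | value | CV% |")
            sections.append("|---|---|---|")
            for _, r in table.iterrows():
                cv = "" if pd.isna(r["cv_percent"]) else f"{r['cv_percent']:.0f}"
                sections.append(f"| {r['parameter']} | {r['value']:.4g} | {cv} |")
            sections.append("")

    path = out / "logic_classification.csv"
    if path.exists():
        found_any = True
        table = pd.read_csv(path)
        sections.append("## Logic behaviour of predicted test circuits\n")
        sections.append("| model | circuit | predicted | expected | mismatch |")
        sections.append("|---|---|---|---|---|")
        for _, r in table.iterrows():
            sections.append(
                f"| {r['model']} | {r['circuit_id']} | {r['predicted']} | "
                f"{r['expected']} | {r['mismatch']} |"
            )
        sections.append("")

    path = out / "prediction_performance.csv"
    if path.exists():
        found_any = True
        table = pd.read_csv(path)
        sections.append("## Prediction performance (observed vs predicted medians)\n")
        for _, r in table.iterrows():
            sections.append(
                f"- {r['model']} {r['observable']}: r = {r['r']:.3f} (n = {r['n']})"
            )
        sections.append("")

    path = out / "model_comparison.json"
    if path.exists():
        found_any = True
        with open(path) as fh:
            cmp_res = json.load(fh)
        sections.append("## Model comparison (likelihood-ratio test, RFP)\n")
        sections.append(
            f"- LR statistic = {cmp_res['statistic']:.2f}, df = {cmp_res['df']}, "
            f"p = {cmp_res['pvalue']:.3g}\n"
        )

    if not found_any:
        raise ValueError(f"no stage outputs found under {out}")
    report = out / "report.md"
    report.write_text("\n".join(sections))
    return report
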