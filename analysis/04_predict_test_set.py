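"""Bottom-up prediction of the unseen test circuits.

Composes the training-fit block parameters into the eight interconnected
test cascades, propagates estimation uncertainty with Monte Carlo bands,
classifies each circuit's logic against its composed-parity expectation,
and scores observed-vs-predicted correlation per observable.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from txcascade.circuits import registry, test_ids
from txcascade.datasets import DoseResponseDataset
from txcascade.predict import plot_bands, predict_circuit, prediction_performance
from txcascade.simulate import default_hsl_grid
from txcascade.steady_state import classify_logic_behaviour
from txcascade.fitting import ParameterDistribution, fit_training_bm, fit_training_nbm
from txcascade.circuits import training_ids

OUT = Path("results")
SEED = 7
N_DRAWS = 150


def main() -> None:
    reg = registry()
    data = DoseResponseDataset.from_csv(OUT / "data" / "dose_response.csv")
    grid = default_hsl_grid()
    mu = data.mu_table()
    observed = data.condition_means()

    runs = []
    for model, boot_csv, ids in (
        ("NBM", OUT / "bootstrap_nbm.csv", test_ids()),
        ("BM", OUT / "bootstrap_bm.csv", test_ids(monitor=True)),
    ):
        dist = ParameterDistribution(pd.read_csv(boot_csv))
        if len(dist.samples) > N_DRAWS:
            dist = ParameterDistribution(dist.samples.sample(N_DRAWS, random_state=SEED))
        if model == "NBM":
            point = fit_training_nbm(data.subset(circuits=training_ids()), seed=SEED)
        else:
            point = fit_training_bm(
                data.subset(circuits=training_ids(monitor=True) + ["Mon_rg"]), seed=SEED
            )
        runs.append((model, dist, point, ids))

    band_frames, logic_rows, perf_frames = [], [], []
    fig, axes = plt.subplots(2, 4, figsize=(18, 7))
    for model, dist, point, ids in runs:
        pred_rows = []
        for k, cid in enumerate(ids):
            topo = reg[cid]
            bands = predict_circuit(topo, dist, point.params, mu, grid, model=model)
            band_frames.append(bands.bands.assign(circuit_id=cid, model=model))
            b = bands.for_observable("RFP")
            pred_rows.append(
                bands.bands.rename(columns={"median": "value"})[
                    ["hsl_nM", "observable", "value"]
                ].assign(circuit_id=cid)
            )
            cls = classify_logic_behaviour(
                [b["median"].iloc[0]], [b["median"].iloc[-1]],
                expected_direction=topo.expected_direction,
            )
            logic_rows.append(dict(model=model, circuit_id=cid, predicted=cls.label,
                                   expected=cls.expected, mismatch=cls.mismatch))
            if model == "NBM":
                plot_bands(bands, observed.rename(columns={"value": "value"}),
                           ax=axes.flat[k])
        perf, _ = prediction_performance(observed, pd.concat(pred_rows))
        perf_frames.append(perf.assign(model=model))

    pd.concat(band_frames).to_csv(OUT / "prediction_bands.csv", index=False)
    logic = pd.DataFrame(logic_rows)
    logic.to_csv(OUT / "logic_classification.csv", index=False)
    perf = pd.concat(perf_frames)
    perf.to_csv(OUT / "prediction_performance.csv", index=False)
    fig.tight_layout()
    fig.savefig(OUT / "test_set_predictions.png", dpi=110)

    print("Observed vs predicted medians (Pearson r):")
    print(perf.to_string(index=False))
    mism = logic[logic["mismatch"]]
    print("\nCircuits whose predicted logic contradicts composed parity:")
    print(mism.to_string(index=False) if len(mism) else "  none")


if __name__ == "__main__":
    main()
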