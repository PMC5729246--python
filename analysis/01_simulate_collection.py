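"""Generate the synthetic circuit-collection dataset.

The in vivo measurements are not deposited, so the whole analysis runs on
synthetic data: steady-state outputs of every circuit (training + test,
with and without the GFP monitor cassette, plus the monitor-only culture)
from the burden model at the packaged training-set parameters, with 3
replicates at 10% CV on a 9-point HSL grid, and growth rates declining
with each strain's burden proxy.  A raw microplate export of the training
set is also emitted for the reduction step.
"""

from pathlib import Path

from txcascade.circuits import test_ids, training_ids
from txcascade.plate import write_plate_csv
from txcascade.simulate import (
    GenerationSpec,
    generate_dose_response,
    plate_wells_from_dose_response,
)

OUT = Path("results/data")
SEED = 2017


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    circuits = (
        training_ids() + test_ids()
        + training_ids(monitor=True) + test_ids(monitor=True)
        + ["Mon_rg"]
    )
    spec = GenerationSpec(seed=SEED, model="BM", truth_column="BM_training",
                          circuits=circuits, cv=0.10)
    data = generate_dose_response(spec)
    data.to_csv(OUT / "dose_response.csv")
    spec.to_yaml(OUT / "generation_spec.yaml")
    print(f"wrote {len(data)} rows for {len(data.circuits)} circuits "
          f"-> {OUT/'dose_response.csv'}")

    # raw plate kinetics for the training circuits (one HSL subset keeps the
    # export small; the reduction step only needs representative wells)
    small = data.subset(circuits=training_ids())
    keep = sorted(small.df["hsl_nM"].unique())[::2]
    small = small.__class__(small.df[small.df["hsl_nM"].isin(keep)])
    wells = plate_wells_from_dose_response(small, seed=SEED + 1)
    write_plate_csv(wells, OUT / "plate_data.csv", OUT / "plate_map.csv")
    print(f"wrote {len(wells)} plate wells -> {OUT/'plate_data.csv'}")


if __name__ == "__main__":
    main()
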