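"""Reduce the raw microplate export to per-cell synthesis rates.

Blanks each well (medium for OD, non-fluorescent culture for red,
fitted exp(q + m*OD) autofluorescence for green), computes growth rate and
dF/dt / OD over the exponential window (0.05 <= OD600 <= 0.18), normalises
to the constitutive reference cultures, and checks the result against the
dose-response table the plates were generated from.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from txcascade.datasets import DoseResponseDataset
from txcascade.plate import dose_response_from_summaries, process_plate, read_plate_csv

OUT = Path("results")
DATA = OUT / "data"


def main() -> None:
    wells = read_plate_csv(DATA / "plate_data.csv", DATA / "plate_map.csv")
    summaries = process_plate(wells)
    summaries.to_csv(OUT / "plate_summaries.csv", index=False)
    tidy = dose_response_from_summaries(summaries)
    tidy.to_csv(OUT / "plate_dose_response.csv", index=False)

    truth = DoseResponseDataset.from_csv(DATA / "dose_response.csv").condition_means()
    est = (
        tidy.groupby(["circuit_id", "hsl_nM", "observable"])["value"].mean().reset_index()
    )
    merged = truth.merge(est, on=["circuit_id", "hsl_nM", "observable"],
                         suffixes=("_table", "_plate"))
    rel = np.abs(merged["value_plate"] - merged["value_table"]) / merged["value_table"]
    print(f"reduced {len(summaries)} wells; {len(merged)} conditions matched the "
          f"generating table")
    print(f"median |relative difference| plate vs table: {rel.median():.3%} "
          f"(95th pct {rel.quantile(0.95):.3%})")
    pd.DataFrame({"median_rel_diff": [rel.median()],
                  "p95_rel_diff": [rel.quantile(0.95)]}).to_csv(
        OUT / "plate_reduction_check.csv", index=False)


if __name__ == "__main__":
    main()
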