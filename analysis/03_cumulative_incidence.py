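#!/usr/bin/env python
"""Fit the two-cause model and tabulate cumulative incidence by year.

Fits the intercept-only competing-risks model to a large simulated cohort
and prints the yearly cumulative incidence of death and transplantation —
the model-based analogue of a registry incidence table — next to the
generating truth's population-averaged values.
"""

import logging
from pathlib import Path

import pandas as pd

from gomprisk.calibration import population_summaries
from gomprisk.cohort import default_config, generate_cohort
from gomprisk.pipeline import cumulative_incidence_table

logging.disable(logging.WARNING)

out_dir = Path(__file__).resolve().parents[1] / "results"
out_dir.mkdir(exist_ok=True)

cfg = default_config(n=5000)
cohort = generate_cohort(cfg, seed=2)
table = cumulative_incidence_table(cohort, years=(1, 2, 3, 4))

truth = population_summaries(default_config(), times=(1, 2, 3, 4))
table["true_death_pct"] = [100 * truth[f"cif_death_{int(y)}y"]
                           for y in table["year"]]
table["true_transplant_pct"] = [100 * truth[f"cif_transplant_{int(y)}y"]
                                for y in table["year"]]

table.to_csv(out_dir / "cumulative_incidence.tsv", sep="\t", index=False)
print(table.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print(f"\nwrote {out_dir / 'cumulative_incidence.tsv'}")
print("note: the fitted columns estimate the marginal incidence of an n=5000 "
      "cohort; the truth columns are the calibrated configuration's "
      "population-averaged sub-distribution functions.")
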