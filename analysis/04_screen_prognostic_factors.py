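#!/usr/bin/env python
"""Run the univariate -> multivariate prognostic-factor screen end to end.

Screens the full Table-style candidate pool (demographics plus labs, most
of them pure noise in the generating truth) on a simulated registry-sized
cohort and on a larger cohort where the true effects are well powered.
Reports land in results/screening_n109/ and results/screening_n1000/.
"""

import logging
from pathlib import Path

from gomprisk.cohort import default_config
from gomprisk.pipeline import PipelineConfig, run_pipeline

logging.disable(logging.WARNING)

base = Path(__file__).resolve().parents[1] / "results"

for n, seed in ((109, 1), (1000, 2)):
    out = base / f"screening_n{n}"
    report = run_pipeline(PipelineConfig(cohort=default_config(n=n),
                                         out_dir=str(out), seed=seed))
    print(f"n={n}: retained (death)      {report.retained[1]}")
    print(f"n={n}: retained (transplant) {report.retained[2]}")
    if len(report.multivariate):
        sig = report.multivariate[report.multivariate.significant]
        pairs = [f"{r.variable}{'[' + r.level + ']' if r.level else ''}"
                 f"->cause{r.outcome}" for r in sig.itertuples()]
        print(f"n={n}: multivariate-significant: {pairs}")
    for note in report.notes:
        print(f"n={n}: note: {note}")
    print(f"n={n}: report at {out / 'report.md'}\n")

print("The true effects in the generating configuration are age, gender, "
      "uric acid and phosphorus band; everything else is noise, so at "
      "registry size (n=109) the liberal univariate screen passes noise "
      "variables at roughly its nominal 25% rate while the larger cohort "
      "concentrates on the real signals.")
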