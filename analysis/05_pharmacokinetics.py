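"""One-compartment PK estimation for every simulated patient profile.

Runs terminal-slope regression, the method of residuals and trapezoidal
AUC on each plasma profile; profiles with too few quantifiable points
(clopidogrel falls below its LLOQ within hours) are listed with the
stage that declared them unestimable.
"""

import logging
from pathlib import Path

import pandas as pd

from chromapk.pipeline import default_config, run_pipeline

OUT = Path(__file__).resolve().parents[1] / "results" / "pipeline"

if __name__ == "__main__":
    logging.basicConfig(level=logging.INFO, format="%(message)s")
    cfg = default_config(seed=1)
    if not list(OUT.glob("profile_*.tsv")):
        run_pipeline(cfg, "simulate", OUT)
    run_pipeline(cfg, "pk", OUT)
    print(pd.read_csv(OUT / "pk_report.tsv", sep="\t").to_string(index=False))
    failures = OUT / "pk_failures.tsv"
    if failures.exists():
        print("--- not estimable ---")
        print(pd.read_csv(failures, sep="\t").to_string(index=False))
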