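"""Accuracy/precision, stability, robustness and degradation tables.

Assesses the simulated QC replicates under the +/-15% recovery and RSD
rule, the stability sets under the same rule, summarizes retention-time
variability under perturbed flow rate and pH, and computes stressed-peak
recovery percentages.
"""

import logging
from pathlib import Path

import pandas as pd

from chromapk.pipeline import default_config, run_pipeline

OUT = Path(__file__).resolve().parents[1] / "results" / "pipeline"

if __name__ == "__main__":
    logging.basicConfig(level=logging.INFO, format="%(message)s")
    cfg = default_config(seed=1)
    if not (OUT / "qc_replicates.tsv").exists():
        run_pipeline(cfg, "simulate", OUT)
    status = run_pipeline(cfg, "validate", OUT)
    for name in ("validation_report", "stability_report", "degradation_report"):
        print(f"--- {name} ---")
        print(pd.read_csv(OUT / f"{name}.tsv", sep="\t").to_string(index=False))
    print("validation:", "PASS" if status == 0 else "FAIL")
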