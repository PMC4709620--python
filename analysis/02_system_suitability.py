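"""Check the simulated chromatographic system against guideline limits.

Detects the four assay peaks, computes plate count, tailing factor and
resolution per analyte, and applies the acceptance limits
(Rs > 2.0, T <= 2.0, N > 2000).
"""

import logging
from pathlib import Path

import pandas as pd

from chromapk.pipeline import default_config, run_pipeline

OUT = Path(__file__).resolve().parents[1] / "results" / "pipeline"

if __name__ == "__main__":
    logging.basicConfig(level=logging.INFO, format="%(message)s")
    cfg = default_config(seed=1)
    if not (OUT / "chromatogram.tsv").exists():
        run_pipeline(cfg, "simulate", OUT)
    status = run_pipeline(cfg, "sst", OUT)
    report = pd.read_csv(OUT / "sst_report.tsv", sep="\t")
    print(report.to_string(index=False))
    print("system suitability:", "PASS" if status == 0 else "FAIL")
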