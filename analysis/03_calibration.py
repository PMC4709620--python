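"""Fit the internal-standard-ratio calibration line per analyte.

Refits the simulated calibration batches (area ratio vs concentration,
ordinary least squares) and prints each regression equation with its
coefficient of determination and working range.
"""

import logging
from pathlib import Path

import yaml

from chromapk.pipeline import default_config, run_pipeline

OUT = Path(__file__).resolve().parents[1] / "results" / "pipeline"

if __name__ == "__main__":
    logging.basicConfig(level=logging.INFO, format="%(message)s")
    cfg = default_config(seed=1)
    if not (OUT / "calibration_CLP.tsv").exists():
        run_pipeline(cfg, "simulate", OUT)
    run_pipeline(cfg, "calibrate", OUT)
    for path in sorted(OUT.glob("curve_*.yaml")):
        rec = yaml.safe_load(path.read_text())
        print(
            f"{rec['analyte']}: {rec['equation']}  r^2 = {rec['r_squared']:.4f}  "
            f"range {rec['range_low']}-{rec['range_high']} ug/mL"
        )
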