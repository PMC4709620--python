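"""Generate every pipeline input with known ground truth.

Writes the simulated chromatogram (four assay peaks on a noisy
baseline), internal-standard calibration batches at the plasma spiking
levels, QC and stability replicate sets, robustness retention-time
runs, and Bateman plasma profiles for three simulated patients on the
0-12 h sampling schedule.
"""

import logging
from pathlib import Path

from chromapk.pipeline import default_config, run_pipeline

OUT = Path(__file__).resolve().parents[1] / "results" / "pipeline"

if __name__ == "__main__":
    logging.basicConfig(level=logging.INFO, format="%(message)s")
    cfg = default_config(seed=1)
    run_pipeline(cfg, "simulate", OUT)
    artifacts = sorted(p.name for p in OUT.glob("*.tsv"))
    print(f"wrote {len(artifacts)} artifacts to {OUT}:")
    for name in artifacts:
        print(f"  {name}")
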