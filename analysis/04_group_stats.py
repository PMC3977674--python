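#!/usr/bin/env python
"""Group-level inference on the demo MMC table and scanpath metrics: the
2 (Task) x 3 (Model) split-plot ANOVA, planned comparisons, and the
between-group t-tests, followed by the plain-text report and summary plot.

Writes results/demo/stats/ and results/demo/report/ and prints the report.
"""

from pathlib import Path

from froa.pipeline import load_config, report, stats

OUT = Path(__file__).resolve().parent.parent / "results" / "demo"

if __name__ == "__main__":
    cfg = load_config("demo")
    stats(cfg, OUT)
    out = report(cfg, OUT)
    print((out / "report.txt").read_text())
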