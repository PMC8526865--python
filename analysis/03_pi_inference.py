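#!/usr/bin/env python
"""Proportion-index inference battery.

Computes PI-by-infant and PI-by-item, tests both against chance with the
two-sided Wilcoxon signed-rank test (Hodges-Lehmann 95% CI, Cohen's d,
JZS Bayes factor), compares age groups with Kruskal-Wallis, and runs the
age / vocabulary / frequency-imbalance correlations with their default-
prior Bayes factors.  Reads results/data/, writes results/inference/.
"""

from pathlib import Path

from lwl.pipeline import RunConfig, run_pipeline

DATA = Path("results/data")
OUT = Path("results/inference")


def main() -> None:
    cfg = RunConfig(input_dir=str(DATA), run_cluster=False, seed=7)
    result = run_pipeline(cfg, out_dir=OUT)
    print(result.summary)
    print(f"tables written to {OUT}/")


if __name__ == "__main__":
    main()
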