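#!/usr/bin/env python
"""Cluster-mass permutation analysis of the gaze time course.

Bins target looking over 0-7,000 ms in 50 ms steps, transforms with
arcsin(sqrt(p)), finds runs of bins with |t| > 2.02 against chance, and
sizes them against 1,000 participant-level sign-flip resamples — for the
whole cohort and each age group.  Reads results/data/, writes
results/cluster/.
"""

from pathlib import Path

import numpy as np

from lwl import cluster as cl
from lwl import preprocess as pp
from lwl.data_model import AGE_GROUPS
from lwl.io import read_dataset, write_results

DATA = Path("results/data")
OUT = Path("results/cluster")
SEED = 7


def main() -> None:
    ds = read_dataset(DATA)
    retained, _ = pp.filter_trials(pp.summarize_trials(ds))
    ages = ds.participant_ages().set_index("participant_id")["age_group"]
    rng = np.random.default_rng(SEED)

    tables = {}
    for name, members in [("all", set(ages.index))] + [
        (g, set(ages.index[ages == g])) for g in AGE_GROUPS
    ]:
        trials = retained.loc[retained["participant_id"].isin(members), "trial_id"]
        ana = cl.cluster_test(ds, trials, seed=rng)
        tables[f"clusters_{name}"] = ana.clusters
        if len(ana.clusters):
            for _, c in ana.clusters.iterrows():
                flag = " *significant*" if c["significant"] else ""
                print(f"[{name}] {c['start_ms']:.0f}-{c['end_ms']:.0f} ms "
                      f"{c['sign'].lower()} cluster, mass {c['mass']:.2f}, "
                      f"p = {c['p']:.3f}{flag}")
        else:
            print(f"[{name}] no supra-threshold clusters")
    write_results(tables, OUT)
    print(f"tables written to {OUT}/")


if __name__ == "__main__":
    main()
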