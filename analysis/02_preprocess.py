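#!/usr/bin/env python
"""Score and filter the cohort's gaze data.

Summarises every trial over the 368-3,505 ms post-naming window, applies
the 12.5% attention filter and the both-trials-per-pair rule, and reports
how much data survives.  Reads results/data/, writes results/preprocess/.
"""

from pathlib import Path

from lwl import pi_frequency as pf
from lwl import preprocess as pp
from lwl.io import read_dataset, write_results

DATA = Path("results/data")
OUT = Path("results/preprocess")


def main() -> None:
    ds = read_dataset(DATA)
    summaries = pp.summarize_trials(ds)
    retained, trial_log = pp.filter_trials(summaries)
    pis, pair_log = pf.pair_pis(retained)
    pis_kept, infant_log = pp.filter_infants(pis)

    write_results(
        {
            "trial_summaries": summaries,
            "retained_trials": retained,
            "trial_exclusions": trial_log,
            "pair_exclusions": pair_log,
            "infant_exclusions": infant_log,
        },
        OUT,
    )
    n_inf = ds.participants.shape[0]
    kept_inf = pis_kept["participant_id"].nunique()
    print(f"trials: {len(retained)}/{len(summaries)} retained "
          f"({len(trial_log)} excluded, mostly low attention)")
    print(f"pairs scored (both trials valid): {len(pis)}; "
          f"mean per infant {len(pis) / n_inf:.2f}")
    print(f"infants with >= 4 scoreable pairs: {kept_inf}/{n_inf}")
    print(f"tables written to {OUT}/")


if __name__ == "__main__":
    main()
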