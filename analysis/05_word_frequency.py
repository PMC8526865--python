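#!/usr/bin/env python
"""Word-frequency imbalance: parental ratings and a toy corpus count.

Builds the parental frequency-imbalance table from the questionnaire,
correlates it with PI-by-item (one-sided, rho > 0, with the default-prior
Bayes factor), and demonstrates the corpus route on generated CHAT
transcripts: children under 33 months contribute case-insensitive token
counts from every speaker except the child.  Reads results/data/ and
results/inference/, writes results/frequency/.
"""

from pathlib import Path

import pandas as pd

from lwl import inference as inf
from lwl import pi_frequency as pf
from lwl.chat import make_chat_fixture
from lwl.io import read_dataset, write_results

DATA = Path("results/data")
OUT = Path("results/frequency")

# Synthetic corpus: per-transcript child ages and adult word counts chosen
# to illustrate the age filter and a heavily imbalanced pair.
TOY_TRANSCRIPTS = [
    ({"car": {"MOT": 160, "FAT": 40}, "plate": {"MOT": 2}}, 24.0),
    ({"car": {"MOT": 120}, "ball": {"MOT": 30, "CHI": 10}}, 30.5),
    ({"plate": {"MOT": 3}, "fork": {"MOT": 8}, "soup": {"MOT": 11}}, 28.0),
    ({"car": {"MOT": 500}}, 40.0),  # too old: excluded by the <33 mo rule
]


def main() -> None:
    ds = read_dataset(DATA)
    imbalance = pf.pair_imbalances(ds.questionnaire, ds.pairs)
    by_item = pd.read_csv("results/inference/pi_by_item.tsv", sep="\t")
    merged = by_item.merge(imbalance, on="pair_id")

    top = imbalance.loc[imbalance["imbalance"].idxmax()]
    low = imbalance.loc[imbalance["imbalance"].idxmin()]
    print(f"mean pair imbalance {imbalance['imbalance'].mean():.2f} Likert points "
          f"(SD {imbalance['imbalance'].std():.2f})")
    print(f"largest: {top['word_a']}-{top['word_b']} ({top['imbalance']:.2f}); "
          f"smallest: {low['word_a']}-{low['word_b']} ({low['imbalance']:.2f})")

    corr = inf.pearson_r(merged["imbalance"], merged["pi_mean"],
                         alternative=inf.POSITIVE)
    bf = inf.bf01_correlation(corr.r, len(merged), direction=inf.POSITIVE)
    print(f"imbalance vs PI-by-item: r({corr.df}) = {corr.r:.2f}, "
          f"one-sided p = {corr.p:.3f}, BF01 = {bf.bf01:.2f} ({bf.evidence_label})")

    docs = [make_chat_fixture(counts, age) for counts, age in TOY_TRANSCRIPTS]
    words = list(ds.pairs["word_a"]) + list(ds.pairs["word_b"])
    counts, warnings = pf.childes_word_counts(docs, words)
    corpus = pf.childes_imbalances(counts, ds.pairs)
    seen = corpus[(corpus["childes_count_a"] + corpus["childes_count_b"]) > 0]
    for _, row in seen.iterrows():
        print(f"corpus counts {row['word_a']}={row['childes_count_a']}, "
              f"{row['word_b']}={row['childes_count_b']} -> "
              f"imbalance {row['childes_imbalance']}")
    write_results({"pair_imbalance": imbalance, "childes_imbalance": corpus}, OUT)
    print(f"tables written to {OUT}/")


if __name__ == "__main__":
    main()
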