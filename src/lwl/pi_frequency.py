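"""Proportion indices, questionnaire summaries, and frequency imbalance.

The proportion index (PI) of a yoked picture pair is

    PI = p1 + p2 - 1,

where p1 and p2 are the target-looking proportions of the pair's two trials
(each picture named once).  Equivalently it is the looking to one image when
it is named minus the looking to the same image when the other is named —
the two anchorings give the identical number, which is why one PI per pair
suffices.  PI ranges from -1 (consistent distractor preference) through 0
(chance) to +1 (consistent target preference).  PI-by-infant averages a
participant's pair PIs; PI-by-item averages one pair's PIs over infants.

Word-frequency imbalance of a pair is the absolute difference of its two
words' frequency measures: mean parental exposure ratings (1-5 Likert) or
corpus token counts from CHAT transcripts.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

from .chat import ChatDocument, ChatError, parse_chat
from .data_model import UNDERSTANDS, UNDERSTANDS_AND_SPEAKS


def pair_pi(p1: float, p2: float) -> float:
    """Proportion index from the two trials' target-looking proportions."""
    return p1 + p2 - 1.0


def pair_pis(trial_summaries: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One PI per participant x yoked pair.

    A pair is scoreable only when both of its trials carry a defined
    p_target; single-trial pairs are skipped and logged.  Returns
    (pair table with columns participant_id, pair_id, p1, p2, pi; skip log).
    """
    valid = trial_summaries.dropna(subset=["p_target"]).sort_values(
        ["participant_id", "pair_id", "half"]
    )
    agg = valid.groupby(["participant_id", "pair_id"], sort=True)["p_target"].agg(
        ["size", "first", "last"]
    )
    complete = agg["size"] == 2
    table = pd.DataFrame(
        {
            "participant_id": agg.index.get_level_values(0)[complete],
            "pair_id": agg.index.get_level_values(1)[complete],
            "p1": agg.loc[complete, "first"].to_numpy(),
            "p2": agg.loc[complete, "last"].to_numpy(),
        }
    )
    table["pi"] = pair_pi(table["p1"], table["p2"])
    incomplete = agg.loc[~complete]
    log = pd.DataFrame(
        {
            "participant_id": incomplete.index.get_level_values(0),
            "unit_id": incomplete.index.get_level_values(1),
            "reason": [f"only {s} valid trial(s)" for s in incomplete["size"]],
        }
    )
    return table.reset_index(drop=True), log.reset_index(drop=True)


def pi_by_infant(pair_pi_table: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean PI per participant over available pairs."""
    agg = pair_pi_table.groupby("participant_id")["pi"].agg(["mean", "size"])
    return agg.rename(columns={"mean": "pi_mean", "size": "n_pairs"}).reset_index()


def pi_by_item(pair_pi_table: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean PI per yoked pair over contributing infants."""
    agg = pair_pi_table.groupby("pair_id")["pi"].agg(["mean", "size"])
    return agg.rename(columns={"mean": "pi_mean", "size": "n_infants"}).reset_index()


def count_understood(
    questionnaire: pd.DataFrame, participant_id: str, target_words: Sequence[str]
) -> int:
    """Number of target words the parent reported as understood (with or
    without production); words missing from the questionnaire count as not
    understood."""
    q = questionnaire[questionnaire["participant_id"] == participant_id]
    status = q.set_index("word")["status"]
    return int(sum(
        status.get(w) in (UNDERSTANDS, UNDERSTANDS_AND_SPEAKS) for w in target_words
    ))


def understood_counts(questionnaire: pd.DataFrame, target_words: Sequence[str]) -> pd.DataFrame:
    """count_understood for every participant in the questionnaire."""
    rows = [
        (pid, count_understood(questionnaire, pid, target_words))
        for pid in sorted(questionnaire["participant_id"].unique())
    ]
    return pd.DataFrame(rows, columns=["participant_id", "n_understood"])


def word_mean_rating(questionnaire: pd.DataFrame, word: str) -> float:
    """Mean 1-5 exposure rating over responding parents."""
    ratings = questionnaire.loc[questionnaire["word"] == word, "exposure"]
    if ratings.empty:
        raise ValueError(f"no exposure ratings for word {word!r}")
    return float(ratings.mean())


def pair_imbalance(mean_a: float, mean_b: float) -> float:
    """Absolute difference of the two words' mean ratings (Likert points)."""
    return abs(mean_a - mean_b)


def pair_imbalances(questionnaire: pd.DataFrame, pairs: pd.DataFrame) -> pd.DataFrame:
    """Parental frequency-imbalance table: one row per yoked pair with the
    per-word mean ratings and their absolute difference."""
    rows = []
    for _, row in pairs.iterrows():
        ma = word_mean_rating(questionnaire, row["word_a"])
        mb = word_mean_rating(questionnaire, row["word_b"])
        rows.append((row["pair_id"], row["word_a"], row["word_b"],
                     ma, mb, pair_imbalance(ma, mb)))
    return pd.DataFrame(
        rows, columns=["pair_id", "word_a", "word_b", "mean_a", "mean_b", "imbalance"]
    )


def childes_word_counts(
    chat_documents: Iterable["str | ChatDocument"],
    target_words: Sequence[str],
    max_age_months: float = 33.0,
) -> tuple[dict[str, int], list[str]]:
    """Corpus token counts per target word over a set of CHAT transcripts.

    Only documents whose target child is younger than ``max_age_months``
    contribute; within a document, tokens are counted case-insensitively and
    exact-orthographically across all speakers except the target child
    (the measure is how often the child *heard* each word).  Unparseable or
    age-less documents are skipped with a warning.  Returns
    (word -> summed count, warnings).
    """
    counts = {w: 0 for w in target_words}
    warnings: list[str] = []
    for i, doc in enumerate(chat_documents):
        if isinstance(doc, str):
            try:
                doc = parse_chat(doc)
            except ChatError as exc:
                warnings.append(f"document {i}: skipped ({exc})")
                continue
        if doc.child_age_months is None:
            warnings.append(f"document {i}: skipped (child age missing)")
            continue
        if doc.child_age_months >= max_age_months:
            continue
        for w in target_words:
            counts[w] += doc.count_word(w, exclude_child=True)
    return counts, warnings


def pair_childes_imbalance(counts: Mapping[str, int], word_a: str, word_b: str) -> int:
    """Absolute corpus-count difference for one pair."""
    for w in (word_a, word_b):
        if w not in counts:
            raise KeyError(f"no corpus count for word {w!r}")
    return abs(int(counts[word_a]) - int(counts[word_b]))


def childes_imbalances(counts: Mapping[str, int], pairs: pd.DataFrame) -> pd.DataFrame:
    """Corpus frequency-imbalance table over all yoked pairs."""
    rows = [
        (row["pair_id"], row["word_a"], row["word_b"],
         int(counts[row["word_a"]]), int(counts[row["word_b"]]),
         pair_childes_imbalance(counts, row["word_a"], row["word_b"]))
        for _, row in pairs.iterrows()
    ]
    return pd.DataFrame(
        rows,
        columns=["pair_id", "word_a", "word_b",
                 "childes_count_a", "childes_count_b", "childes_imbalance"],
    )
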