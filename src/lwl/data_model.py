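"""Shared data model for two-alternative infant gaze experiments.

The experiment presents two pictures side by side while naming one of them
(the "looking-while-listening" paradigm).  Gaze is sampled at 60 Hz over a
trial spanning -1,000 ... 7,000 ms around picture onset; each sample is
classified into one of four look categories.  Trials come in yoked pairs:
the same two pictures appear twice, each picture named once, which makes the
pair's proportion index independent of which picture anchors it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Look categories for one gaze sample.
LEFT_AOI = "LEFT_AOI"
RIGHT_AOI = "RIGHT_AOI"
ONSCREEN_OTHER = "ONSCREEN_OTHER"
OFFSCREEN_OR_INVALID = "OFFSCREEN_OR_INVALID"
LABELS = (LEFT_AOI, RIGHT_AOI, ONSCREEN_OTHER, OFFSCREEN_OR_INVALID)

# Sides a target picture can occupy.
LEFT = "LEFT"
RIGHT = "RIGHT"

# Parental judgement of word comprehension.
UNDERSTANDS = "UNDERSTANDS"
UNDERSTANDS_AND_SPEAKS = "UNDERSTANDS_AND_SPEAKS"
DOES_NOT_UNDERSTAND = "DOES_NOT_UNDERSTAND"
STATUSES = (UNDERSTANDS, UNDERSTANDS_AND_SPEAKS, DOES_NOT_UNDERSTAND)

# Age groups, months computed as age_days / 30 (30-day months).
G6_7 = "G6_7"
G8_10 = "G8_10"
G11_14 = "G11_14"
AGE_GROUPS = (G6_7, G8_10, G11_14)

SAMPLE_HZ = 60.0
SAMPLE_STEP_MS = 1000.0 / SAMPLE_HZ
TRIAL_START_MS = -1000.0
TRIAL_END_MS = 7000.0
#: Number of 60 Hz samples on the closed grid -1,000 ... 7,000 ms.
SAMPLES_PER_TRIAL = 481

GAZE_COLUMNS = ["participant_id", "trial_id", "t_ms", "label"]
GAZE_XY_COLUMNS = ["participant_id", "trial_id", "t_ms", "x", "y", "valid"]
DESIGN_COLUMNS = [
    "participant_id",
    "trial_id",
    "pair_id",
    "target_word",
    "target_side",
    "target_onset_ms",
    "half",
]
PAIRS_COLUMNS = ["pair_id", "word_a", "word_b"]
PARTICIPANTS_COLUMNS = ["participant_id", "age_days"]
QUESTIONNAIRE_COLUMNS = ["participant_id", "word", "status", "exposure"]


class SchemaError(ValueError):
    """A table does not carry the documented columns/value domains."""


class IntegrityError(ValueError):
    """Cross-table identifiers do not line up."""


def age_months(age_days: "int | np.ndarray | pd.Series") -> "float | np.ndarray | pd.Series":
    """Age in 30-day months."""
    return np.asarray(age_days, dtype=float) / 30.0


def age_group(months: "float | np.ndarray | pd.Series") -> "str | np.ndarray":
    """Assign the age group: <8 months, 8-<11 months, >=11 months."""
    m = np.asarray(months, dtype=float)
    out = np.where(m < 8.0, G6_7, np.where(m < 11.0, G8_10, G11_14))
    return out.item() if out.ndim == 0 else out


@dataclass
class Dataset:
    """Cross-linked tidy tables of one experiment (real or simulated).

    gaze:          participant_id, trial_id, t_ms, label  (or x, y, valid)
    design:        participant_id, trial_id, pair_id, target_word,
                   target_side, target_onset_ms, half
    pairs:         pair_id, word_a, word_b
    participants:  participant_id, age_days
    questionnaire: participant_id, word, status, exposure
    """

    gaze: pd.DataFrame
    design: pd.DataFrame
    pairs: pd.DataFrame
    participants: pd.DataFrame
    questionnaire: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=QUESTIONNAIRE_COLUMNS)
    )

    def validate(self) -> "Dataset":
        """Check referential integrity; raise IntegrityError on violation."""
        design_trials = set(self.design["trial_id"])
        gaze_trials = set(self.gaze["trial_id"])
        orphans = gaze_trials - design_trials
        if orphans:
            raise IntegrityError(
                f"gaze references trial_id(s) absent from design: {sorted(orphans)[:5]}"
            )
        pair_ids = set(self.pairs["pair_id"])
        missing_pairs = set(self.design["pair_id"]) - pair_ids
        if missing_pairs:
            raise IntegrityError(
                f"design references pair_id(s) absent from pairs: {sorted(missing_pairs)[:5]}"
            )
        known_participants = set(self.participants["participant_id"])
        for name, table in (("gaze", self.gaze), ("design", self.design)):
            unknown = set(table["participant_id"]) - known_participants
            if unknown:
                raise IntegrityError(
                    f"{name} references unknown participant_id(s): {sorted(unknown)[:5]}"
                )
        if "label" in self.gaze.columns:
            bad = set(self.gaze["label"].unique()) - set(LABELS)
            if bad:
                raise SchemaError(f"gaze label(s) outside the four categories: {sorted(bad)}")
        t = self.gaze["t_ms"].to_numpy(dtype=float)
        if len(t) and (t.min() < TRIAL_START_MS - 1e-6 or t.max() > TRIAL_END_MS + 1e-6):
            raise SchemaError("gaze t_ms outside the trial span [-1000, 7000] ms")
        return self

    def participant_ages(self) -> pd.DataFrame:
        """participants table augmented with age_months and age_group."""
        out = self.participants.copy()
        out["age_months"] = age_months(out["age_days"])
        out["age_group"] = age_group(out["age_months"].to_numpy())
        return out
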