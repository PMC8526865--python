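"""Reading and writing the tidy analysis tables.

All tables are delimited text (tab by default), UTF-8, with fixed column
order.  Unknown extra columns are preserved.  Writing is deterministic:
identical inputs produce byte-identical files.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Mapping

import pandas as pd

from .data_model import (
    DESIGN_COLUMNS,
    GAZE_COLUMNS,
    GAZE_XY_COLUMNS,
    PAIRS_COLUMNS,
    PARTICIPANTS_COLUMNS,
    QUESTIONNAIRE_COLUMNS,
    Dataset,
    SchemaError,
)

_SEP = "\t"


def _read_table(path: "str | Path", required: list[str], name: str,
                alt_required: "list[str] | None" = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    for req in (required, alt_required) if alt_required else (required,):
        missing = [c for c in req if c not in df.columns]
        if not missing:
            return df
    raise SchemaError(f"{name} table at {path} lacks required column(s): {missing}")


def _numeric(df: pd.DataFrame, column: str, name: str, integer: bool = False) -> pd.Series:
    raw = df[column]
    out = pd.to_numeric(raw, errors="coerce")
    bad = out.isna() & raw.notna()
    if bad.any():
        row = int(bad.idxmax())
        raise SchemaError(
            f"{name}.{column}: non-numeric value {raw[row]!r} at row {row}"
        )
    return out.astype(int) if integer else out.astype(float)


def load_dataset(
    gaze_path: "str | Path",
    design_path: "str | Path",
    participants_path: "str | Path",
    pairs_path: "str | Path",
    questionnaire_path: "str | Path | None" = None,
) -> Dataset:
    """Load and validate the five tables into a :class:`Dataset`.

    The gaze table may carry either a ``label`` column (pre-classified
    looks) or raw ``x, y, valid`` columns; in the latter case look
    classification is deferred to :func:`lwl.preprocess.classify_samples`.
    """
    gaze = _read_table(gaze_path, GAZE_COLUMNS, "gaze", alt_required=GAZE_XY_COLUMNS)
    gaze["t_ms"] = _numeric(gaze, "t_ms", "gaze")
    if "label" not in gaze.columns:
        gaze["x"] = _numeric(gaze, "x", "gaze")
        gaze["y"] = _numeric(gaze, "y", "gaze")
        gaze["valid"] = gaze["valid"].astype(str).str.lower().isin(("true", "1", "yes"))
    else:
        gaze["label"] = pd.Categorical(gaze["label"])

    design = _read_table(design_path, DESIGN_COLUMNS, "design")
    design["target_onset_ms"] = _numeric(design, "target_onset_ms", "design")
    design["half"] = _numeric(design, "half", "design", integer=True)

    pairs = _read_table(pairs_path, PAIRS_COLUMNS, "pairs")
    participants = _read_table(participants_path, PARTICIPANTS_COLUMNS, "participants")
    participants["age_days"] = _numeric(participants, "age_days", "participants", integer=True)

    if questionnaire_path is not None:
        questionnaire = _read_table(questionnaire_path, QUESTIONNAIRE_COLUMNS, "questionnaire")
        questionnaire["exposure"] = _numeric(questionnaire, "exposure", "questionnaire",
                                             integer=True)
    else:
        questionnaire = pd.DataFrame(columns=QUESTIONNAIRE_COLUMNS)

    return Dataset(gaze=gaze, design=design, pairs=pairs,
                   participants=participants, questionnaire=questionnaire).validate()


def write_table(df: pd.DataFrame, path: "str | Path") -> Path:
    """Write one table deterministically (UTF-8, tab-separated, LF endings)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_SEP, index=False, lineterminator="\n", encoding="utf-8")
    return path


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: "str | Path") -> dict[str, Path]:
    """Write each named result table to ``out_dir/<name>.tsv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not os.access(out_dir, os.W_OK):
        raise OSError(f"output directory not writable: {out_dir}")
    return {name: write_table(df, out_dir / f"{name}.tsv") for name, df in tables.items()}


def write_dataset(dataset: Dataset, out_dir: "str | Path") -> dict[str, Path]:
    """Write a whole dataset as its five tables."""
    return write_results(
        {
            "gaze": dataset.gaze,
            "design": dataset.design,
            "pairs": dataset.pairs,
            "participants": dataset.participants,
            "questionnaire": dataset.questionnaire,
        },
        out_dir,
    )


def read_dataset(in_dir: "str | Path") -> Dataset:
    """Load a dataset previously written by :func:`write_dataset`."""
    in_dir = Path(in_dir)
    q = in_dir / "questionnaire.tsv"
    return load_dataset(
        in_dir / "gaze.tsv",
        in_dir / "design.tsv",
        in_dir / "participants.tsv",
        in_dir / "pairs.tsv",
        q if q.exists() else None,
    )
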