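"""Look classification, window extraction, and exclusion rules.

Three filters reproduce the reference preprocessing chain:

* trial level: trials with less than 12.5% valid on-screen looking during
  the stimulus presentation (0-7,000 ms) are discarded as fussy;
* pair level: a yoked pair yields a proportion index only if both of its
  trials survive;
* infant level: infants contributing fewer than 4 of the 14 pairs are
  excluded.

"Looking to the screen" for the attention filter means any valid on-screen
sample (either picture region or the background between them); the pre-trial
second (-1,000 ... 0 ms) does not count toward it.  The target-looking
proportion p_target uses picture-region samples only (target + distractor)
as its denominator — the convention under which the yoked-pair proportion
index is exactly anchor-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import (
    LEFT,
    LEFT_AOI,
    OFFSCREEN_OR_INVALID,
    ONSCREEN_OTHER,
    RIGHT_AOI,
    Dataset,
)

#: Post-naming scoring window, ms relative to target-word onset, half-open.
DEFAULT_WINDOW_MS = (368.0, 3505.0)
#: Minimum fraction of valid on-screen looking per trial.
MIN_ATTENTION = 0.125
#: Minimum number of scoreable yoked pairs per infant.
MIN_PAIRS = 4

EXCLUSION_COLUMNS = ["participant_id", "unit_id", "reason"]


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class AOIGeometry:
    """Screen layout: two picture rectangles (x0, y0, x1, y1) in pixels."""

    left: tuple[float, float, float, float]
    right: tuple[float, float, float, float]
    screen_w: float = 1920.0
    screen_h: float = 1080.0

    def __post_init__(self) -> None:
        lx0, ly0, lx1, ly1 = self.left
        rx0, ry0, rx1, ry1 = self.right
        if lx1 > rx0 and rx1 > lx0 and ly1 > ry0 and ry1 > ly0:
            raise GeometryError("left and right picture rectangles overlap")


#: 750 px square pictures centred 500 px left/right of a 1920x1080 screen
#: centre, mirroring the reference display layout.
DEFAULT_GEOMETRY = AOIGeometry(
    left=(85.0, 165.0, 835.0, 915.0),
    right=(1085.0, 165.0, 1835.0, 915.0),
)


def classify_samples(
    x: np.ndarray, y: np.ndarray, valid: np.ndarray,
    geometry: AOIGeometry = DEFAULT_GEOMETRY,
) -> np.ndarray:
    """Vectorised gaze-point classification into the four look categories."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    on_screen = valid & (x >= 0) & (x < geometry.screen_w) & (y >= 0) & (y < geometry.screen_h)

    def inside(rect):
        x0, y0, x1, y1 = rect
        return (x >= x0) & (x < x1) & (y >= y0) & (y < y1)

    out = np.full(x.shape, ONSCREEN_OTHER, dtype=object)
    out[inside(geometry.left)] = LEFT_AOI
    out[inside(geometry.right)] = RIGHT_AOI
    out[~on_screen] = OFFSCREEN_OR_INVALID
    return out


def classify_sample(x: float, y: float, valid: bool,
                    geometry: AOIGeometry = DEFAULT_GEOMETRY) -> str:
    """Classify a single gaze point."""
    return classify_samples(np.array([x]), np.array([y]), np.array([valid]), geometry)[0]


#: Canonical label order used for fast integer coding.
_LABEL_ORDER = (LEFT_AOI, RIGHT_AOI, ONSCREEN_OTHER, OFFSCREEN_OR_INVALID)


def label_codes(label: pd.Series) -> np.ndarray:
    """Map the label column to int8 codes 0..3 in canonical order."""
    cat = label if isinstance(label.dtype, pd.CategoricalDtype) else pd.Categorical(label)
    cat = cat if not isinstance(cat, pd.Series) else cat.array
    mapping = np.array([_LABEL_ORDER.index(c) for c in cat.categories], dtype=np.int8)
    return mapping[cat.codes]


def ensure_labels(dataset: Dataset, geometry: AOIGeometry = DEFAULT_GEOMETRY) -> Dataset:
    """Classify raw x/y gaze into labels if the label column is absent."""
    if "label" in dataset.gaze.columns:
        return dataset
    gaze = dataset.gaze.copy()
    gaze["label"] = pd.Categorical(
        classify_samples(gaze["x"].to_numpy(), gaze["y"].to_numpy(),
                         gaze["valid"].to_numpy(), geometry)
    )
    return Dataset(gaze=gaze, design=dataset.design, pairs=dataset.pairs,
                   participants=dataset.participants, questionnaire=dataset.questionnaire)


def summarize_trials(
    dataset: Dataset, window_ms: tuple[float, float] = DEFAULT_WINDOW_MS
) -> pd.DataFrame:
    """Per-trial look summary.

    Counts samples whose time relative to target onset lies in
    [window_ms[0], window_ms[1]): n_target, n_distractor, n_other_onscreen,
    n_off; p_target = n_target / (n_target + n_distractor) (NaN when no
    picture-region looks fall in the window); attention = valid on-screen
    samples over [0, 7000) ms divided by all samples in [0, 7000) ms.
    """
    dataset = ensure_labels(dataset)
    design = dataset.design.set_index("trial_id")
    if design.index.has_duplicates:
        raise ValueError("duplicate trial_id in design")

    g = dataset.gaze
    trial_codes, uniq_trials = pd.factorize(g["trial_id"], sort=False)
    n_trials = len(uniq_trials)
    design_u = design.loc[uniq_trials]
    t = g["t_ms"].to_numpy(dtype=float)
    label_code = label_codes(g["label"])

    onset = design_u["target_onset_ms"].to_numpy(dtype=float)[trial_codes]
    target_left = (design_u["target_side"] == LEFT).to_numpy()[trial_codes]
    rel = t - onset
    in_window = (rel >= window_ms[0]) & (rel < window_ms[1])
    in_trial = (t >= 0.0) & (t < 7000.0)

    is_left, is_right = label_code == 0, label_code == 1
    is_target = np.where(target_left, is_left, is_right)
    is_aoi = is_left | is_right
    is_on = label_code != 3

    def count(mask):
        return np.bincount(trial_codes[mask], minlength=n_trials).astype(np.int64)

    n_trial_samples = count(np.ones(len(t), dtype=bool))
    if (n_trial_samples == 0).any():
        raise ValueError("trial with no samples")
    agg = pd.DataFrame(
        {
            "trial_id": uniq_trials,
            "n_target": count(in_window & is_target),
            "n_distractor": count(in_window & is_aoi & ~is_target),
            "n_other_onscreen": count(in_window & (label_code == 2)),
            "n_off": count(in_window & (label_code == 3)),
            "n_window": count(in_window),
        }
    )
    n_on_trial = count(in_trial & is_on)
    n_in_trial = count(in_trial)

    aoi = (agg["n_target"] + agg["n_distractor"]).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        agg["p_target"] = np.where(aoi > 0, agg["n_target"] / np.where(aoi > 0, aoi, 1), np.nan)
        agg["attention"] = np.where(n_in_trial > 0, n_on_trial / np.maximum(n_in_trial, 1), 0.0)
    out = agg.merge(
        dataset.design[["trial_id", "participant_id", "pair_id", "half"]],
        on="trial_id", how="left",
    )
    cols = ["participant_id", "trial_id", "pair_id", "half", "n_target",
            "n_distractor", "n_other_onscreen", "n_off", "n_window",
            "p_target", "attention"]
    return out[cols]


def filter_trials(
    summaries: pd.DataFrame, min_attention: float = MIN_ATTENTION
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop fussy trials (attention strictly below ``min_attention``) and
    trials with no scoreable picture looks; return (retained, exclusion log)."""
    fussy = summaries["attention"] < min_attention
    no_aoi = ~fussy & summaries["p_target"].isna()
    log_rows = []
    for mask, reason in ((fussy, f"attention < {min_attention}"),
                         (no_aoi, "no AOI looks in window")):
        for _, row in summaries.loc[mask].iterrows():
            log_rows.append((row["participant_id"], row["trial_id"], reason))
    retained = summaries.loc[~(fussy | no_aoi)].reset_index(drop=True)
    log = pd.DataFrame(log_rows, columns=EXCLUSION_COLUMNS)
    return retained, log


def filter_infants(
    pair_pis: pd.DataFrame, min_pairs: int = MIN_PAIRS
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep infants providing at least ``min_pairs`` scoreable yoked pairs."""
    counts = pair_pis.groupby("participant_id")["pair_id"].nunique()
    dropped = counts.index[counts < min_pairs]
    log = pd.DataFrame(
        [(pid, "", f"pairs with PI = {counts[pid]} < {min_pairs}") for pid in dropped],
        columns=EXCLUSION_COLUMNS,
    )
    retained = pair_pis[~pair_pis["participant_id"].isin(set(dropped))].reset_index(drop=True)
    return retained, log


def exclude_rare_pairs(
    dataset: Dataset, questionnaire: "pd.DataFrame | None" = None
) -> tuple[Dataset, pd.DataFrame]:
    """Per infant, drop every yoked pair where the parent rated either word's
    exposure 1 ("rarely"); pairs with a missing rating are retained and
    logged.  Returns the filtered dataset plus an exclusion log."""
    q = dataset.questionnaire if questionnaire is None else questionnaire
    ratings = q.set_index(["participant_id", "word"])["exposure"]
    design = dataset.design.merge(dataset.pairs, on="pair_id", how="left")

    drop_keys: set[tuple[str, str]] = set()
    log_rows = []
    for (pid, pair_id), grp in design.groupby(["participant_id", "pair_id"], sort=False):
        word_a, word_b = grp["word_a"].iloc[0], grp["word_b"].iloc[0]
        ra = ratings.get((pid, word_a))
        rb = ratings.get((pid, word_b))
        if ra is None or rb is None:
            log_rows.append((pid, pair_id, "missing exposure rating; pair retained"))
            continue
        if ra == 1 or rb == 1:
            drop_keys.add((pid, pair_id))
            log_rows.append((pid, pair_id, 'exposure rated 1 ("rarely")'))

    keys = list(zip(dataset.design["participant_id"], dataset.design["pair_id"]))
    keep_trial = ~pd.Series([k in drop_keys for k in keys]).to_numpy()
    design_kept = dataset.design.loc[keep_trial]
    kept_trials = set(design_kept["trial_id"])
    gaze_kept = dataset.gaze[dataset.gaze["trial_id"].isin(kept_trials)]
    filtered = Dataset(
        gaze=gaze_kept.reset_index(drop=True),
        design=design_kept.reset_index(drop=True),
        pairs=dataset.pairs,
        participants=dataset.participants,
        questionnaire=dataset.questionnaire,
    )
    return filtered, pd.DataFrame(log_rows, columns=EXCLUSION_COLUMNS)
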