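"""Synthetic infant-gaze generator with known ground truth.

The generator emulates the structure the analysis assumes: each infant sees
14 yoked picture pairs twice (once per experiment half, each picture named
once, sides counterbalanced), with 60 Hz gaze samples over -1,000 ... 7,000 ms
around picture onset.

Looking is modelled as a two-state (target/distractor) first-order dwell
chain at the sample level.  Before the named word has been heard (plus a
saccade latency) the chain is symmetric; afterwards its stationary
target-looking probability shifts from 0.5 to 0.5 + delta_ij, where

    delta_ij = clamp(delta + infant_effect_i + beta * imbalance_j)

combines a population bias, a per-infant deviation (SD tau) and an item
effect proportional to the pair's word-frequency imbalance.  Off-screen
excursions ride on top as an independent two-state on/off chain; "fussy"
trials use a much higher off-screen hazard so they fall below the attention
filter downstream.  Brief ONSCREEN_OTHER samples are emitted while the gaze
travels between the two picture regions.

A matching parental questionnaire (comprehension status and 1-5 exposure
ratings with noise around per-word true exposures) and toy CHAT transcripts
(see :mod:`lwl.chat`) round out the inputs the downstream stages need.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    LEFT,
    LEFT_AOI,
    OFFSCREEN_OR_INVALID,
    ONSCREEN_OTHER,
    RIGHT,
    RIGHT_AOI,
    SAMPLES_PER_TRIAL,
    TRIAL_START_MS,
    Dataset,
    UNDERSTANDS,
    UNDERSTANDS_AND_SPEAKS,
    DOES_NOT_UNDERSTAND,
    age_months,
)

#: 60 Hz sample grid, -1,000 ... 7,000 ms inclusive.
T_GRID_MS = TRIAL_START_MS + np.arange(SAMPLES_PER_TRIAL) * (1000.0 / 60.0)

#: Reference stimulus set: (word_a, word_b, true_exposure_a, true_exposure_b).
#: Exposures live on the 1-5 parental Likert scale; the named anchor pairs
#: (brush-diaper, bottle-hat) carry the reported mean ratings, and the mean
#: absolute pair imbalance of the set is ~1.01 Likert points.
DEFAULT_PAIRS: tuple[tuple[str, str, float, float], ...] = (
    ("bottle", "hat", 3.67, 3.72),
    ("brush", "diaper", 2.26, 4.68),
    ("car", "plate", 3.90, 2.90),
    ("fork", "soup", 2.80, 2.90),
    ("baby", "bird", 4.20, 3.00),
    ("ball", "book", 4.00, 3.60),
    ("dog", "cat", 4.30, 3.10),
    ("banana", "cheese", 3.80, 2.30),
    ("cup", "spoon", 3.50, 3.30),
    ("shoe", "sock", 3.90, 3.00),
    ("bed", "bath", 4.50, 3.00),
    ("apple", "cookie", 3.70, 2.20),
    ("nose", "hand", 4.10, 3.50),
    ("light", "door", 3.20, 4.80),
)

# Age-group day ranges used when drawing participants (30-day months).
_GROUP_AGE_DAYS = ((183, 239), (240, 329), (330, 449))


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Generative-model parameters.

    Probabilities are per 60 Hz sample.  ``stay_prob`` sets the dwell-chain
    persistence (mean dwell = 16.7 ms / (1 - stay_prob)); the switch-rate
    scale c = 2 * (1 - stay_prob) keeps overall gaze mobility comparable
    across bias levels.
    """

    n_per_group: int = 14
    pairs: Sequence[tuple[str, str, float, float]] = DEFAULT_PAIRS
    # Reference effect structure: a positive item effect of frequency
    # imbalance riding on a population bias chosen so the grand-mean naming
    # bias is ~0 (delta + beta * mean imbalance of DEFAULT_PAIRS ~ 0),
    # emulating a cohort with chance-level overall preference but
    # imbalance-driven item differences.
    delta: float = -0.03
    tau: float = 0.05
    beta: float = 0.03
    latency_mean_ms: float = 300.0
    latency_sd_ms: float = 100.0
    stay_prob: float = 0.95
    p_off: float = 0.02
    p_return: float = 0.15
    fuss_prob: float = 0.12
    fuss_p_off: float = 0.30
    fuss_p_return: float = 0.02
    rating_sd: float = 0.7
    n_transition_other: int = 1
    target_onset_ms: float = 3000.0
    #: Optional (start, end) ms relative to target onset outside of which the
    #: naming bias is switched off (latency then ignored); None = bias active
    #: from target onset + latency to trial end.
    bias_window_ms: "tuple[float, float] | None" = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("stay_prob", "p_off", "p_return", "fuss_prob",
                     "fuss_p_off", "fuss_p_return"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if not (0.0 < self.stay_prob < 1.0):
            raise ConfigError("stay_prob must lie strictly inside (0, 1)")
        if abs(self.delta) > 0.5:
            raise ConfigError("delta must lie in [-0.5, 0.5]")
        if self.latency_sd_ms < 0 or self.latency_mean_ms < 0:
            raise ConfigError("latency parameters must be non-negative")
        words = [w for p in self.pairs for w in p[:2]]
        if len(set(words)) != len(words):
            raise ConfigError("pair words must be distinct")

    @property
    def n_infants(self) -> int:
        return 3 * self.n_per_group

    @property
    def target_words(self) -> list[str]:
        return [w for p in self.pairs for w in p[:2]]

    def pair_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pair_id": [f"pair{i + 1:02d}" for i in range(len(self.pairs))],
                "word_a": [p[0] for p in self.pairs],
                "word_b": [p[1] for p in self.pairs],
            }
        )

    def true_imbalances(self) -> np.ndarray:
        """|true_exposure_a - true_exposure_b| per pair, in Likert points."""
        return np.array([abs(p[2] - p[3]) for p in self.pairs])


def _draw_latencies(rng: np.random.Generator, cfg: SimConfig, n: int) -> np.ndarray:
    """Truncated-normal saccade latencies, lower bound 0 ms."""
    if cfg.latency_sd_ms == 0:
        return np.full(n, cfg.latency_mean_ms)
    a = (0.0 - cfg.latency_mean_ms) / cfg.latency_sd_ms
    return stats.truncnorm.rvs(
        a, np.inf, loc=cfg.latency_mean_ms, scale=cfg.latency_sd_ms,
        size=n, random_state=rng,
    )


def _simulate_chains(
    rng: np.random.Generator,
    cfg: SimConfig,
    pstar: np.ndarray,
    active: np.ndarray,
    fussy: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run dwell and on/off chains for all trials at once.

    pstar:  (n_trials,) stationary target probability once the bias is on.
    active: (n_trials, K) bool, bias active for the transition into sample k.
    Returns (on_target, off_screen, switched) boolean arrays (n_trials, K).
    """
    n_trials, K = active.shape
    c = 2.0 * (1.0 - cfg.stay_prob)
    p_off = np.where(fussy, cfg.fuss_p_off, cfg.p_off)
    p_ret = np.where(fussy, cfg.fuss_p_return, cfg.p_return)

    z = np.empty((n_trials, K), dtype=bool)
    off = np.empty((n_trials, K), dtype=bool)
    switched = np.zeros((n_trials, K), dtype=bool)

    z[:, 0] = rng.random(n_trials) < 0.5
    with np.errstate(divide="ignore", invalid="ignore"):
        occ = np.where(p_off + p_ret > 0, p_off / np.maximum(p_off + p_ret, 1e-12), 0.0)
    off[:, 0] = rng.random(n_trials) < occ

    for k in range(1, K):
        p_eff = np.where(active[:, k], pstar, 0.5)
        p_switch = np.where(z[:, k - 1], c * (1.0 - p_eff), c * p_eff)
        flip = rng.random(n_trials) < p_switch
        z[:, k] = z[:, k - 1] ^ flip
        switched[:, k] = flip
        u = rng.random(n_trials)
        off[:, k] = np.where(off[:, k - 1], u >= p_ret, u < p_off)
    return z, off, switched


def simulate_dataset(config: SimConfig, emit_coordinates: bool = False) -> Dataset:
    """Generate one full dataset (gaze, design, pairs, participants,
    questionnaire) under ``config``; identical config implies identical data.

    With ``emit_coordinates`` the gaze table carries raw ``x, y, valid``
    columns (representative points inside the picture regions of
    :data:`lwl.preprocess.DEFAULT_GEOMETRY`) instead of pre-classified labels.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_pairs = len(cfg.pairs)
    pair_ids = [f"pair{i + 1:02d}" for i in range(n_pairs)]
    imbalance = cfg.true_imbalances()

    # Participants: n_per_group per age group.
    pids, ages = [], []
    for g, (lo, hi) in enumerate(_GROUP_AGE_DAYS):
        for j in range(cfg.n_per_group):
            pids.append(f"p{g * cfg.n_per_group + j + 1:03d}")
            ages.append(int(rng.integers(lo, hi + 1)))
    participants = pd.DataFrame({"participant_id": pids, "age_days": ages})
    infant_effect = rng.normal(0.0, cfg.tau, size=len(pids)) if cfg.tau > 0 else np.zeros(len(pids))

    # Trial design: per infant, each pair once per half; sides and naming
    # order counterbalanced at random; order shuffled within each half.
    design_rows = []
    for i, pid in enumerate(pids):
        sides = rng.random(n_pairs) < 0.5          # True: word_a on the left
        a_first = rng.random(n_pairs) < 0.5        # True: word_a named in half 1
        for half in (1, 2):
            order = rng.permutation(n_pairs)
            for slot, j in enumerate(order):
                word_a, word_b, _, _ = cfg.pairs[j]
                named_a = a_first[j] if half == 1 else not a_first[j]
                target_word = word_a if named_a else word_b
                a_side = LEFT if sides[j] else RIGHT
                b_side = RIGHT if sides[j] else LEFT
                target_side = a_side if named_a else b_side
                k = (half - 1) * n_pairs + slot
                design_rows.append(
                    (pid, f"{pid}_t{k:02d}", pair_ids[j], target_word,
                     target_side, cfg.target_onset_ms, half, i, j)
                )
    design = pd.DataFrame(
        design_rows,
        columns=["participant_id", "trial_id", "pair_id", "target_word",
                 "target_side", "target_onset_ms", "half", "_i", "_j"],
    )

    n_trials = len(design)
    delta_ij = np.clip(
        cfg.delta + infant_effect[design["_i"]] + cfg.beta * imbalance[design["_j"]],
        -0.49, 0.49,
    )
    pstar = np.clip(0.5 + delta_ij, 0.01, 0.99)

    onset = design["target_onset_ms"].to_numpy(dtype=float)
    if cfg.bias_window_ms is None:
        latency = _draw_latencies(rng, cfg, n_trials)
        t0 = onset + latency
        active = T_GRID_MS[None, :] >= t0[:, None]
    else:
        lo, hi = cfg.bias_window_ms
        rel = T_GRID_MS[None, :] - onset[:, None]
        active = (rel >= lo) & (rel < hi)
    fussy = rng.random(n_trials) < cfg.fuss_prob

    z, off, switched = _simulate_chains(rng, cfg, pstar, active, fussy)

    # Travelling gaze: the first n_transition_other samples after a dwell
    # switch land between the pictures.
    other = np.zeros_like(switched)
    for lag in range(cfg.n_transition_other):
        if lag == 0:
            other |= switched
        else:
            other[:, lag:] |= switched[:, :-lag]

    target_left = (design["target_side"] == LEFT).to_numpy()[:, None]
    on_left = z == target_left  # looking at the left picture
    # Label codes: 0 LEFT_AOI, 1 RIGHT_AOI, 2 ONSCREEN_OTHER, 3 OFFSCREEN.
    codes = np.where(on_left, 0, 1)
    codes = np.where(other, 2, codes)
    codes = np.where(off, 3, codes)

    gaze = pd.DataFrame(
        {
            "participant_id": np.repeat(design["participant_id"].to_numpy(), SAMPLES_PER_TRIAL),
            "trial_id": np.repeat(design["trial_id"].to_numpy(), SAMPLES_PER_TRIAL),
            "t_ms": np.tile(T_GRID_MS, n_trials),
        }
    )
    if emit_coordinates:
        from .preprocess import DEFAULT_GEOMETRY as g

        flat = codes.ravel()
        cx = np.select(
            [flat == 0, flat == 1, flat == 2],
            [(g.left[0] + g.left[2]) / 2, (g.right[0] + g.right[2]) / 2, g.screen_w / 2],
            default=-100.0,
        )
        cy = np.where(flat == 3, -100.0, (g.left[1] + g.left[3]) / 2)
        gaze["x"] = cx
        gaze["y"] = cy
        gaze["valid"] = flat != 3
    else:
        gaze["label"] = pd.Categorical.from_codes(
            codes.ravel(),
            categories=[LEFT_AOI, RIGHT_AOI, ONSCREEN_OTHER, OFFSCREEN_OR_INVALID],
        )

    questionnaire = _simulate_questionnaire(rng, cfg, participants)
    design = design.drop(columns=["_i", "_j"])
    return Dataset(
        gaze=gaze,
        design=design,
        pairs=cfg.pair_table(),
        participants=participants,
        questionnaire=questionnaire,
    )


def _simulate_questionnaire(
    rng: np.random.Generator, cfg: SimConfig, participants: pd.DataFrame
) -> pd.DataFrame:
    """Likert ratings = clamp(round(true_exposure + N(0, rating_sd)), 1, 5);
    comprehension probability grows with age and with true exposure."""
    words, true_expo = [], []
    for word_a, word_b, ea, eb in cfg.pairs:
        words += [word_a, word_b]
        true_expo += [ea, eb]
    true_expo = np.array(true_expo)
    months = age_months(participants["age_days"].to_numpy())

    rows = []
    for pid, m in zip(participants["participant_id"], months):
        noise = rng.normal(0.0, cfg.rating_sd, size=len(words)) if cfg.rating_sd > 0 else 0.0
        rating = np.clip(np.round(true_expo + noise), 1, 5).astype(int)
        p_und = 1.0 / (1.0 + np.exp(-(0.35 * (m - 10.5) + 0.5 * (true_expo - 3.0))))
        understood = rng.random(len(words)) < p_und
        speaks = rng.random(len(words)) < np.clip(0.05 * (m - 8.0), 0.0, 0.5)
        status = np.where(
            understood,
            np.where(speaks, UNDERSTANDS_AND_SPEAKS, UNDERSTANDS),
            DOES_NOT_UNDERSTAND,
        )
        for w, s, r in zip(words, status, rating):
            rows.append((pid, w, s, int(r)))
    return pd.DataFrame(rows, columns=["participant_id", "word", "status", "exposure"])


def expected_pi(
    config: SimConfig,
    window_ms: tuple[float, float] = (368.0, 3505.0),
    latency_grid: int = 801,
) -> float:
    """Analytic expectation of the pair proportion index under a homogeneous
    configuration (tau = 0, beta = 0).

    The proportion index of a yoked pair is p1 + p2 - 1; within each trial
    the dwell chain's target probability q_k relaxes geometrically from 0.5
    toward 0.5 + delta once the naming bias is active, and the trial's
    scored proportion averages over window samples that remain in a picture
    region.  Because the sample on which the gaze arrives after a dwell
    switch is recoded as a between-picture look, scored samples are the
    *non-arrival* ones, so the per-sample expectation is
    P(target, no switch) / P(no switch) — slightly above q_k whenever the
    leave-rate from the target is the smaller one.  The recursion below
    propagates q_k exactly and weights window samples by their probability
    of being scoreable; the truncated-normal latency is integrated on a
    grid.  Off-screen excursions are independent of the dwell state and
    drop out.
    """
    cfg = config
    if cfg.tau != 0 or cfg.beta != 0:
        raise ConfigError("expected_pi supports only homogeneous configs (tau=0, beta=0)")
    if cfg.bias_window_ms is not None:
        raise ConfigError("expected_pi does not support a restricted bias window")
    if cfg.n_transition_other not in (0, 1):
        raise ConfigError("expected_pi supports n_transition_other in {0, 1} only")
    mask_arrivals = cfg.n_transition_other == 1
    c = 2.0 * (1.0 - cfg.stay_prob)
    rel = T_GRID_MS - cfg.target_onset_ms
    in_window = (rel >= window_ms[0]) & (rel < window_ms[1])
    pstar_on = float(np.clip(0.5 + cfg.delta, 0.01, 0.99))

    if cfg.latency_sd_ms == 0:
        lat = np.array([cfg.latency_mean_ms])
        weights = np.array([1.0])
    else:
        a = (0.0 - cfg.latency_mean_ms) / cfg.latency_sd_ms
        hi = cfg.latency_mean_ms + 6.0 * cfg.latency_sd_ms
        lat = np.linspace(0.0, hi, latency_grid)
        weights = stats.truncnorm.pdf(
            (lat - cfg.latency_mean_ms) / cfg.latency_sd_ms, a, np.inf
        )
        weights /= weights.sum()

    t0 = cfg.target_onset_ms + lat                      # (L,)
    active = T_GRID_MS[None, :] >= t0[:, None]          # (L, K)
    L = len(lat)
    q = np.full(L, 0.5)
    num = np.zeros(L)
    den = np.zeros(L)
    for k in range(1, len(T_GRID_MS)):
        pstar = np.where(active[:, k], pstar_on, 0.5)
        c_td = c * (1.0 - pstar)                        # leave target
        c_dt = c * pstar                                # leave distractor
        stay_t = q * (1.0 - c_td)
        stay_d = (1.0 - q) * (1.0 - c_dt)
        q_next = q * (1.0 - c_td) + (1.0 - q) * c_dt
        if in_window[k]:
            if mask_arrivals:
                num += stay_t
                den += stay_t + stay_d
            else:
                num += q_next
                den += 1.0
        q = q_next
    p_hat = num / den
    return float(2.0 * (weights @ p_hat) - 1.0)


def null_config(**overrides) -> SimConfig:
    """Convenience: a no-effect configuration (delta = tau = beta = 0)."""
    base = dict(delta=0.0, tau=0.0, beta=0.0)
    base.update(overrides)
    return SimConfig(**base)


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    return replace(config, seed=seed)
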