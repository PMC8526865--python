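"""Cluster-based permutation test of target looking against chance.

Per participant, target-looking proportions (target / (target + distractor)
samples, pooled over retained trials) are binned over the 0-7,000 ms trial
time course, variance-stabilised with y = arcsin(sqrt(p)), and expressed as
deviations from chance, y - arcsin(sqrt(0.5)).  A one-sample t statistic
across participants is computed per bin (algebraically identical to the
paired test against a constant chance series); maximal runs of adjacent
bins with |t| above a threshold form signed clusters whose mass is the sum
of their t values.

The null distribution of the maximum absolute cluster mass is built by
flipping the sign of each participant's entire deviation series with
probability 1/2 — the standard exchangeability argument for one-sample
cluster tests, which preserves each participant's temporal autocorrelation.
A participant-resampling bootstrap of the mean-centred deviations is
available as an alternative resampling scheme.  Each observed cluster's
p-value is the fraction of resamples whose maximum |mass| reaches the
observed |mass|.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import LEFT, Dataset
from .preprocess import ensure_labels, label_codes

DEFAULT_BIN_MS = 50.0
DEFAULT_THRESHOLD = 2.02
DEFAULT_RESAMPLES = 1000
CHANCE_Y = math.asin(math.sqrt(0.5))  # pi/4

SIGNFLIP = "signflip"
BOOTSTRAP = "bootstrap"


def arcsine_sqrt(p):
    """Variance-stabilising transform for proportions; maps 0.5 to pi/4."""
    return np.arcsin(np.sqrt(p))


def bin_proportions(
    dataset: Dataset,
    retained_trial_ids,
    bin_ms: float = DEFAULT_BIN_MS,
    span: tuple[float, float] = (0.0, 7000.0),
) -> pd.DataFrame:
    """Per participant x time bin: pooled look counts and the transformed
    target proportion.  Bins with no picture-region samples are missing
    rows, not zeros."""
    dataset = ensure_labels(dataset)
    retained = set(retained_trial_ids)
    g = dataset.gaze[dataset.gaze["trial_id"].isin(retained)]
    if g.empty:
        raise ValueError("no retained trials to bin")
    design = dataset.design.set_index("trial_id")

    t = g["t_ms"].to_numpy(dtype=float)
    in_span = (t >= span[0]) & (t < span[1])
    g = g.loc[in_span]
    t = t[in_span]
    code = label_codes(g["label"])
    trial_codes, uniq_trials = pd.factorize(g["trial_id"], sort=False)
    target_left = (design["target_side"].loc[uniq_trials] == LEFT).to_numpy()[trial_codes]
    is_left, is_right = code == 0, code == 1
    is_target = np.where(target_left, is_left, is_right)
    is_aoi = is_left | is_right

    n_bins = int(math.ceil((span[1] - span[0]) / bin_ms))
    bin_idx = np.floor((t - span[0]) / bin_ms).astype(np.int64)
    pid_codes, uniq_pids = pd.factorize(g["participant_id"], sort=True)
    key = pid_codes * n_bins + bin_idx
    size = len(uniq_pids) * n_bins
    n_target = np.bincount(key[is_target], minlength=size)
    n_aoi = np.bincount(key[is_aoi], minlength=size)

    nz = np.nonzero(n_aoi > 0)[0]
    agg = pd.DataFrame(
        {
            "participant_id": np.asarray(uniq_pids)[nz // n_bins],
            "bin_start_ms": span[0] + (nz % n_bins) * bin_ms,
            "n_target": n_target[nz].astype(np.int64),
            "n_aoi": n_aoi[nz].astype(np.int64),
        }
    )
    agg["p_target"] = agg["n_target"] / agg["n_aoi"]
    agg["y"] = arcsine_sqrt(agg["p_target"])
    agg["deviation"] = agg["y"] - CHANCE_Y
    return agg


def deviation_matrix(
    series: pd.DataFrame,
    bin_ms: float = DEFAULT_BIN_MS,
    span: tuple[float, float] = (0.0, 7000.0),
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Pivot the binned series into a (participants x bins) deviation matrix
    (NaN where a participant has no data in a bin)."""
    n_bins = int(round((span[1] - span[0]) / bin_ms))
    bin_starts = span[0] + np.arange(n_bins) * bin_ms
    wide = series.pivot(index="participant_id", columns="bin_start_ms", values="deviation")
    wide = wide.reindex(columns=bin_starts)
    return wide.to_numpy(dtype=float), bin_starts, list(wide.index)


def _t_for_signs(X0: np.ndarray, mask: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """One-sample t per bin for sign-flipped data, vectorised over resamples.

    X0 is the deviation matrix with NaNs zeroed; per-bin sums of squares are
    invariant under sign flips, so only the means move.
    """
    n_b = mask.sum(axis=0).astype(float)          # participants per bin
    ss_b = (X0**2).sum(axis=0)
    sums = signs @ X0                              # (R, B)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / n_b
        var = (ss_b - n_b * mean**2) / (n_b - 1.0)
        var = np.where(var > 1e-300, var, np.nan)  # zero-variance bins: skip
        tt = mean / np.sqrt(var / n_b)
    tt[:, n_b < 2] = np.nan
    return tt


def per_bin_t(matrix: np.ndarray) -> np.ndarray:
    """Observed one-sample t of the deviations per bin (NaN where fewer than
    two participants contribute or the variance is zero)."""
    X = np.asarray(matrix, dtype=float)
    mask = ~np.isnan(X)
    X0 = np.where(mask, X, 0.0)
    return _t_for_signs(X0, mask, np.ones((1, X.shape[0])))[0]


def find_clusters(
    t_series: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    bin_starts: "np.ndarray | None" = None,
    bin_ms: float = DEFAULT_BIN_MS,
) -> pd.DataFrame:
    """Maximal runs of adjacent bins with t beyond +/-threshold.

    Missing (NaN) bins break adjacency.  Mass is the sum of t over the run;
    sign is POSITIVE/NEGATIVE.
    """
    t = np.asarray(t_series, dtype=float)
    if bin_starts is None:
        bin_starts = np.arange(len(t)) * bin_ms
    state = np.zeros(len(t), dtype=np.int8)
    with np.errstate(invalid="ignore"):
        state[t > threshold] = 1
        state[t < -threshold] = -1
    rows = []
    start = None
    for k in range(len(t) + 1):
        s = state[k] if k < len(t) else 0
        if start is not None and (k == len(t) or s != state[start]):
            run = slice(start, k)
            rows.append(
                (
                    float(bin_starts[start]),
                    float(bin_starts[k - 1] + bin_ms),
                    "POSITIVE" if state[start] > 0 else "NEGATIVE",
                    float(t[run].sum()),
                    k - start,
                )
            )
            start = None
        if k < len(t) and s != 0 and start is None:
            start = k
    return pd.DataFrame(rows, columns=["start_ms", "end_ms", "sign", "mass", "n_bins"])


def _max_abs_masses(tt: np.ndarray, threshold: float) -> np.ndarray:
    """Maximum |cluster mass| per resample row (0 when no cluster forms)."""
    R, B = tt.shape
    out = np.zeros(R)
    for r in range(R):
        t = tt[r]
        best = 0.0
        acc = 0.0
        sign = 0
        for k in range(B + 1):
            if k < B and np.isfinite(t[k]) and abs(t[k]) > threshold:
                s = 1 if t[k] > 0 else -1
                if s != sign and sign != 0:
                    best = max(best, abs(acc))
                    acc = 0.0
                sign = s
                acc += t[k]
            else:
                if sign != 0:
                    best = max(best, abs(acc))
                    acc, sign = 0.0, 0
        out[r] = best
    return out


def permutation_null(
    matrix: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    n_resamples: int = DEFAULT_RESAMPLES,
    seed: "int | np.random.Generator" = 0,
    mode: str = SIGNFLIP,
) -> np.ndarray:
    """Null distribution of the maximum absolute cluster mass.

    ``signflip`` (default): each resample multiplies every participant's
    whole deviation series by an independent +/-1.  ``bootstrap``:
    participants of the mean-centred matrix are resampled with replacement.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = np.asarray(matrix, dtype=float)
    P, _ = X.shape
    mask = ~np.isnan(X)
    if mode == SIGNFLIP:
        X0 = np.where(mask, X, 0.0)
        signs = rng.integers(0, 2, size=(n_resamples, P)) * 2 - 1
        tt = _t_for_signs(X0, mask, signs.astype(float))
    elif mode == BOOTSTRAP:
        col_mean = np.nanmean(np.where(mask, X, np.nan), axis=0)
        centred = X - col_mean[None, :]
        tt = np.empty((n_resamples, X.shape[1]))
        for r in range(n_resamples):
            idx = rng.integers(0, P, size=P)
            tt[r] = per_bin_t(centred[idx])
    else:
        raise ValueError(f"unknown resampling mode {mode!r}")
    return _max_abs_masses(tt, threshold)


def cluster_p_values(
    masses: np.ndarray, null_max_mass: np.ndarray, add_one: bool = False
) -> np.ndarray:
    """p per observed cluster: fraction of resamples whose maximum |mass|
    reaches the cluster's |mass| (optionally (b+1)/(B+1) smoothed)."""
    null = np.asarray(null_max_mass, dtype=float)
    b = (null[None, :] >= np.abs(np.asarray(masses, dtype=float))[:, None]).sum(axis=1)
    B = len(null)
    return (b + 1) / (B + 1) if add_one else b / B


@dataclass
class ClusterAnalysis:
    series: pd.DataFrame
    clusters: pd.DataFrame
    null_max_mass: np.ndarray
    threshold: float
    n_resamples: int
    mode: str


def cluster_test(
    dataset: Dataset,
    retained_trial_ids,
    bin_ms: float = DEFAULT_BIN_MS,
    threshold: float = DEFAULT_THRESHOLD,
    n_resamples: int = DEFAULT_RESAMPLES,
    seed: "int | np.random.Generator" = 0,
    mode: str = SIGNFLIP,
    add_one: bool = False,
) -> ClusterAnalysis:
    """Full cluster permutation analysis of one participant set.

    Cluster p = (#resamples with max |mass| >= |observed mass|) / n_resamples
    (optionally the (b+1)/(B+1) smoothed estimate); clusters with p < 0.05
    are flagged significant.
    """
    series = bin_proportions(dataset, retained_trial_ids, bin_ms=bin_ms)
    X, bin_starts, _ = deviation_matrix(series, bin_ms=bin_ms)
    t_obs = per_bin_t(X)
    clusters = find_clusters(t_obs, threshold=threshold, bin_starts=bin_starts, bin_ms=bin_ms)
    null = permutation_null(X, threshold=threshold, n_resamples=n_resamples,
                            seed=seed, mode=mode)
    if len(clusters):
        clusters["p"] = cluster_p_values(clusters["mass"].to_numpy(), null, add_one)
        clusters["significant"] = clusters["p"] < 0.05
    else:
        clusters["p"] = pd.Series(dtype=float)
        clusters["significant"] = pd.Series(dtype=bool)
    return ClusterAnalysis(series=series, clusters=clusters, null_max_mass=null,
                           threshold=threshold, n_resamples=n_resamples, mode=mode)
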