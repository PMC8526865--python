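import numpy as np
import pandas as pd
import pytest

from conftest import manual_trial_dataset
from lwl import pi_frequency as pf
from lwl import preprocess as pp
from lwl.data_model import (
    LEFT_AOI,
    OFFSCREEN_OR_INVALID,
    ONSCREEN_OTHER,
    RIGHT_AOI,
)
from lwl.simulate import SimConfig, simulate_dataset


def test_classify_sample_regions():
    g = pp.DEFAULT_GEOMETRY
    lx = (g.left[0] + g.left[2]) / 2
    ly = (g.left[1] + g.left[3]) / 2
    assert pp.classify_sample(lx, ly, True) == LEFT_AOI
    rx = (g.right[0] + g.right[2]) / 2
    assert pp.classify_sample(rx, ly, True) == RIGHT_AOI
    assert pp.classify_sample(g.screen_w / 2, ly, True) == ONSCREEN_OTHER
    assert pp.classify_sample(lx, ly, False) == OFFSCREEN_OR_INVALID
    assert pp.classify_sample(-5.0, ly, True) == OFFSCREEN_OR_INVALID


def test_overlapping_aoi_rectangles_rejected():
    with pytest.raises(pp.GeometryError):
        pp.AOIGeometry(left=(0, 0, 1000, 900), right=(900, 0, 1900, 900))


def test_coordinate_dataset_classifies_like_labelled_one():
    cfg = SimConfig(n_per_group=1, seed=13)
    labelled = simulate_dataset(cfg)
    coords = pp.ensure_labels(simulate_dataset(cfg, emit_coordinates=True))
    assert (labelled.gaze["label"].astype(str).to_numpy()
            == coords.gaze["label"].astype(str).to_numpy()).all()


def test_summarize_trial_window_arithmetic():
    """30 target + 10 distractor samples inside the scoring window."""
    labels = [OFFSCREEN_OR_INVALID] * 481
    # onset 3000 -> window [3368, 6505); grid index k has t = -1000 + k/0.06
    window_idx = [k for k, t in enumerate(np.arange(481) * (1000 / 60) - 1000)
                  if 3368 <= t < 6505]
    for k in window_idx[:30]:
        labels[k] = LEFT_AOI
    for k in window_idx[30:40]:
        labels[k] = RIGHT_AOI
    ds = manual_trial_dataset(labels, target_side="LEFT")
    s = pp.summarize_trials(ds).iloc[0]
    assert s["n_target"] == 30 and s["n_distractor"] == 10
    assert s["p_target"] == pytest.approx(0.75)
    assert s["n_window"] == len(window_idx)


def test_all_offscreen_trial_has_no_p_target_and_zero_attention():
    ds = manual_trial_dataset([OFFSCREEN_OR_INVALID] * 481)
    s = pp.summarize_trials(ds).iloc[0]
    assert np.isnan(s["p_target"])
    assert s["attention"] == 0.0


def test_attention_fraction_and_strict_filter_boundary():
    """40 valid on-screen samples of the 420 in 0..7000 ms -> 0.0952, excluded;
    the 12.5% criterion itself is strict 'below'."""
    labels = [OFFSCREEN_OR_INVALID] * 481
    grid = np.arange(481) * (1000 / 60) - 1000
    trial_idx = [k for k, t in enumerate(grid) if 0 <= t < 7000]
    assert len(trial_idx) == 420
    # place the 40 on-screen samples inside the scoring window so the trial
    # is excluded by the attention rule alone
    window_idx = [k for k, t in enumerate(grid) if 3368 <= t < 6505]
    for k in window_idx[:40]:
        labels[k] = LEFT_AOI
    ds = manual_trial_dataset(labels)
    s = pp.summarize_trials(ds)
    assert s.iloc[0]["attention"] == pytest.approx(40 / 420)
    retained, log = pp.filter_trials(s)
    assert len(retained) == 0 and log.iloc[0]["reason"].startswith("attention")

    exact = s.copy()
    exact.loc[0, "attention"] = 0.125  # boundary: retained
    retained2, _ = pp.filter_trials(exact)
    assert len(retained2) == 1


def test_attentive_trial_without_aoi_looks_excluded_with_reason():
    labels = [ONSCREEN_OTHER] * 481
    ds = manual_trial_dataset(labels)
    retained, log = pp.filter_trials(pp.summarize_trials(ds))
    assert len(retained) == 0
    assert log.iloc[0]["reason"] == "no AOI looks in window"


def test_sample_count_conservation(medium_dataset):
    s = pp.summarize_trials(medium_dataset)
    total = s["n_target"] + s["n_distractor"] + s["n_other_onscreen"] + s["n_off"]
    assert (total == s["n_window"]).all()


def test_filters_idempotent(medium_dataset):
    s = pp.summarize_trials(medium_dataset)
    once, log1 = pp.filter_trials(s)
    twice, log2 = pp.filter_trials(once)
    pd.testing.assert_frame_equal(once, twice)
    assert len(log2) == 0
    assert len(log1) == len(s) - len(once)

    pis, _ = pf.pair_pis(once)
    f1, _ = pp.filter_infants(pis)
    f2, flog = pp.filter_infants(f1)
    pd.testing.assert_frame_equal(f1, f2)
    assert len(flog) == 0


def test_min_pairs_boundary():
    pis = pd.DataFrame(
        {
            "participant_id": ["a"] * 3 + ["b"] * 4,
            "pair_id": [f"pair{i}" for i in range(3)] + [f"pair{i}" for i in range(4)],
            "pi": 0.1,
        }
    )
    retained, log = pp.filter_infants(pis)
    assert set(retained["participant_id"]) == {"b"}  # 4 pairs kept, 3 dropped
    assert log.iloc[0]["participant_id"] == "a"


def test_generator_ground_truth_infant_exclusion():
    """Infants whose surviving pairs fall below 4 are exactly the excluded."""
    cfg = SimConfig(n_per_group=7, fuss_prob=0.55, seed=33)
    ds = simulate_dataset(cfg)
    retained, _ = pp.filter_trials(pp.summarize_trials(ds))
    pis, _ = pf.pair_pis(retained)
    counts = pis.groupby("participant_id")["pair_id"].nunique()
    expect_drop = {pid for pid in ds.participants["participant_id"]
                   if counts.get(pid, 0) < 4}
    assert expect_drop  # the fussiness level actually bites
    kept, log = pp.filter_infants(pis)
    assert set(log["participant_id"]) == expect_drop - {
        p for p in expect_drop if counts.get(p, 0) == 0}
    assert set(kept["participant_id"]).isdisjoint(expect_drop)


def test_rare_pair_exclusion_is_per_infant():
    ds = simulate_dataset(SimConfig(n_per_group=1, rating_sd=0.0, seed=1))
    q = ds.questionnaire.copy()
    q["exposure"] = q["exposure"].clip(lower=2)
    pids = list(ds.participants["participant_id"])
    # infant A rates 'bottle' as rarely heard; infant B rates it 4
    q.loc[(q["participant_id"] == pids[0]) & (q["word"] == "bottle"), "exposure"] = 1
    q.loc[(q["participant_id"] == pids[1]) & (q["word"] == "bottle"), "exposure"] = 4
    filtered, log = pp.exclude_rare_pairs(ds, q)
    dropped = set(zip(log.loc[log["reason"].str.contains("rarely"), "participant_id"],
                      log.loc[log["reason"].str.contains("rarely"), "unit_id"]))
    assert dropped == {(pids[0], "pair01")}
    per_infant = filtered.design.groupby("participant_id").size()
    assert per_infant[pids[0]] == 26 and per_infant[pids[1]] == 28
    # gaze rows follow the design
    assert len(filtered.gaze) == len(filtered.design) * 481


def test_rare_pair_missing_rating_retained_and_logged():
    ds = simulate_dataset(SimConfig(n_per_group=1, rating_sd=0.0, seed=1))
    q = ds.questionnaire[ds.questionnaire["word"] != "bottle"].copy()
    q["exposure"] = q["exposure"].clip(lower=2)
    filtered, log = pp.exclude_rare_pairs(ds, q)
    assert len(filtered.design) == len(ds.design)
    assert (log["reason"] == "missing exposure rating; pair retained").all()
    assert set(log["unit_id"]) == {"pair01"}
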