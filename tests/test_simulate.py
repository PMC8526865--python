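import numpy as np
import pandas as pd
import pytest

from lwl import pi_frequency as pf
from lwl import preprocess as pp
from lwl.simulate import (
    ConfigError,
    SimConfig,
    T_GRID_MS,
    expected_pi,
    null_config,
    simulate_dataset,
    with_seed,
)


def mean_pi_by_infant(dataset):
    summaries = pp.summarize_trials(dataset)
    retained, _ = pp.filter_trials(summaries)
    pis, _ = pf.pair_pis(retained)
    pis, _ = pp.filter_infants(pis)
    return pf.pi_by_infant(pis)["pi_mean"].mean()


def test_grid_is_60hz_over_trial_span():
    assert len(T_GRID_MS) == 481
    assert T_GRID_MS[0] == -1000.0
    assert T_GRID_MS[-1] == pytest.approx(7000.0)
    np.testing.assert_allclose(np.diff(T_GRID_MS), 1000.0 / 60.0)


def test_determinism_identical_config_identical_data():
    cfg = SimConfig(n_per_group=2, seed=9)
    a = simulate_dataset(cfg)
    b = simulate_dataset(cfg)
    for name in ("gaze", "design", "participants", "questionnaire"):
        pd.testing.assert_frame_equal(getattr(a, name), getattr(b, name))
    c = simulate_dataset(with_seed(cfg, 10))
    assert not a.gaze["label"].equals(c.gaze["label"])


def test_design_structure_yoked_pairs():
    ds = simulate_dataset(SimConfig(n_per_group=2, seed=5))
    for pid, grp in ds.design.groupby("participant_id"):
        assert len(grp) == 28
        per_pair = grp.groupby("pair_id")
        assert (per_pair.size() == 2).all()
        # each member named once, once per half, same side within infant
        for _, pair_trials in per_pair:
            assert set(pair_trials["half"]) == {1, 2}
            assert len(set(pair_trials["target_word"])) == 2
        # target sides are consistent with one fixed side assignment per pair
        merged = grp.merge(ds.pairs, on="pair_id")
        a_named = merged["target_word"] == merged["word_a"]
        side_of_a = merged["target_side"].where(a_named, merged["target_side"].map(
            {"LEFT": "RIGHT", "RIGHT": "LEFT"}))
        assert (merged.assign(s=side_of_a).groupby("pair_id")["s"].nunique() == 1).all()


def test_invalid_probabilities_rejected():
    with pytest.raises(ConfigError):
        SimConfig(stay_prob=1.2)
    with pytest.raises(ConfigError):
        SimConfig(delta=0.7)
    with pytest.raises(ConfigError):
        SimConfig(p_off=-0.1)


def test_questionnaire_ratings_in_range_and_noiseless_recovery():
    ds = simulate_dataset(SimConfig(n_per_group=2, rating_sd=0.0, seed=2))
    q = ds.questionnaire
    assert q["exposure"].between(1, 5).all()
    truth = {w: e for a, b, ea, eb in SimConfig().pairs for w, e in ((a, ea), (b, eb))}
    got = q.groupby("word")["exposure"].first()
    for word, expo in truth.items():
        assert got[word] == int(np.clip(round(expo), 1, 5))


def test_fussy_trials_fail_attention_filter():
    cfg = SimConfig(n_per_group=1, fuss_prob=1.0, fuss_p_off=0.9,
                    fuss_p_return=0.01, seed=4)
    summaries = pp.summarize_trials(simulate_dataset(cfg))
    retained, log = pp.filter_trials(summaries)
    assert len(retained) == 0
    assert len(log) == len(summaries)


def test_null_calibration_mean_pi_near_zero():
    """delta = tau = beta = 0 gives mean PI-by-infant ~ 0 at ~500 infants."""
    ds = simulate_dataset(null_config(n_per_group=167, seed=11))
    assert abs(mean_pi_by_infant(ds)) < 0.02


def test_mean_pi_nondecreasing_in_delta():
    means = []
    for delta in (0.0, 0.1, 0.2, 0.3):
        cfg = SimConfig(n_per_group=67, delta=delta, tau=0.0, beta=0.0, seed=21)
        means.append(mean_pi_by_infant(simulate_dataset(cfg)))
    assert all(b > a for a, b in zip(means, means[1:]))


def test_expected_pi_limits_and_homogeneity_guard():
    assert expected_pi(null_config()) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ConfigError):
        expected_pi(SimConfig(tau=0.1, beta=0.0))
    # full-window, instant-mixing limit without transit recoding:
    # every window sample sits at the shifted stationary point, E[PI] = 2 delta
    cfg = SimConfig(delta=0.25, tau=0.0, beta=0.0, latency_mean_ms=0.0,
                    latency_sd_ms=0.0, stay_prob=0.5, target_onset_ms=0.0,
                    n_transition_other=0)
    assert expected_pi(cfg, window_ms=(368.0, 3505.0)) == pytest.approx(0.5, abs=1e-6)
    with pytest.raises(ConfigError):
        expected_pi(SimConfig(tau=0.0, beta=0.0, n_transition_other=2))


def test_expected_pi_matches_chain_simulation_oracle():
    """Analytic window-weighted relaxation vs brute-force dwell-chain runs."""
    cfg = SimConfig(delta=0.2, tau=0.0, beta=0.0, latency_mean_ms=300.0,
                    latency_sd_ms=0.0)
    c = 2 * (1 - cfg.stay_prob)
    rel = T_GRID_MS - cfg.target_onset_ms
    in_win = (rel >= 368.0) & (rel < 3505.0)
    t0 = cfg.target_onset_ms + cfg.latency_mean_ms
    rng = np.random.default_rng(0)
    n_rep = 30000
    z = rng.random(n_rep) < 0.5
    n_target = np.zeros(n_rep)
    n_aoi = np.zeros(n_rep)
    for k in range(1, len(T_GRID_MS)):
        pstar = 0.5 + cfg.delta if T_GRID_MS[k] >= t0 else 0.5
        p_switch = np.where(z, c * (1 - pstar), c * pstar)
        flip = rng.random(n_rep) < p_switch
        z = z ^ flip
        if in_win[k]:
            # arrival samples are recoded as between-picture looks and do
            # not enter the scored proportion
            n_target += z & ~flip
            n_aoi += ~flip
    mc = 2 * ((n_target / n_aoi).mean() - 0.5)
    assert expected_pi(cfg) == pytest.approx(mc, abs=0.01)
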