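"""Generator contracts: protocol counts, determinism, planted effects."""

import dataclasses
from collections import Counter

import numpy as np
import pytest
from scipy import stats

from bcistate.features import band_powers, dft_coefficient_powers
from bcistate.synthetic import (GaussianBumpSurface, GeneratorConfig,
                                ConstantSurface, LinearSurface, REST, TASKS,
                                generate_online_session,
                                generate_training_session, surface_from_dict,
                                two_class_training_trials,
                                _synthesize_signals, _rng)


def test_training_session_protocol(small_config):
    """One session: 150 trials, 30 per class, 15 x 1280 signals."""
    trials = generate_training_session(small_config, 0, 0)
    assert len(trials) == 150
    counts = Counter(t.task for t in trials)
    assert all(counts[c] == 30 for c in (REST, *TASKS))
    assert trials[0].signal.shape == (15, 1280)
    assert all((t.label == "rest") == (t.task == REST) for t in trials)


def test_two_sessions_give_60_trials_per_task(small_config):
    counts = Counter()
    for s in range(2):
        counts.update(t.task for t in generate_training_session(small_config, 0, s))
    assert all(counts[c] == 60 for c in (REST, *TASKS))
    two_class = two_class_training_trials(small_config, 0)
    assert sum(t.label == "active" for t in two_class) == 60
    assert sum(t.label == "rest" for t in two_class) == 60


def test_fixed_seed_reproduces_identical_output(small_config):
    a = generate_training_session(small_config, 0, 0)
    b = generate_training_session(small_config, 0, 0)
    assert all(np.array_equal(x.signal, y.signal) for x, y in zip(a, b))
    ia = generate_online_session(small_config, 1, 0)
    ib = generate_online_session(small_config, 1, 0)
    for u, v in zip(ia, ib):
        assert u.ratings == v.ratings and u.true_index == v.true_index
        assert all(np.array_equal(x.signal, y.signal)
                   for x, y in zip(u.trials, v.trials))


def test_online_session_structure(small_config):
    inters = generate_online_session(small_config, 0, 0)
    assert len(inters) == small_config.intersections_per_session
    for it in inters:
        assert 2 <= it.n_directions <= 4
        labels = [t.label for t in it.trials]
        assert labels.count("active") == 1
        assert labels.index("active") == it.true_index
        assert all(t.ratings == it.ratings for t in it.trials)
        assert all(0.0 <= r <= 1.0 for r in it.ratings)


def test_zero_effect_classes_identically_distributed():
    """With effect_amplitude = 0, per-band t statistics between active and
    rest trials stay within sampling noise (|t| < 4 on >= 28/30 bands)."""
    cfg = GeneratorConfig(n_participants=1, effect_amplitude=0.0, seed=7)
    trials = generate_training_session(cfg, 0, 0)
    active = [t for t in trials if t.task == "word_gen"]
    rest = [t for t in trials if t.task == REST]
    pa = np.stack([band_powers(t.signal, cfg.sampling_rate) for t in active])
    pr = np.stack([band_powers(t.signal, cfg.sampling_rate) for t in rest])
    # average over channels -> one value per band per trial
    t_stats = stats.ttest_ind(pa.mean(axis=1), pr.mean(axis=1), axis=0).statistic
    assert np.sum(np.abs(t_stats) < 4) >= 28


def test_planted_effect_lands_in_base_band():
    """With a 10-12 Hz base band the active-minus-rest mean band-power
    difference is positive exactly in bands 10 and 11 on active channels."""
    cfg = GeneratorConfig(n_participants=1, effect_amplitude=0.5,
                          participant_sd=0.0, seed=11)
    trials = []
    for s in range(2):
        trials += generate_training_session(cfg, 0, s)
    active = [t for t in trials if t.task == "word_gen"]
    rest = [t for t in trials if t.task == REST]
    ch = cfg.active_channels[0]
    pa = np.stack([band_powers(t.signal[ch], cfg.sampling_rate) for t in active])
    pr = np.stack([band_powers(t.signal[ch], cfg.sampling_rate) for t in rest])
    t_stats = stats.ttest_ind(pa, pr, axis=0).statistic
    # strong planted shift in the base band, none elsewhere
    assert t_stats[10] > 5 and t_stats[11] > 5
    others = np.delete(t_stats, [10, 11])
    assert np.sum(np.abs(others) < 4) >= 26
    # planted power magnitude: each 1-Hz bin carries a sinusoid of power
    # A^2/2 on top of the (cancelling) background
    diff = (pa.mean(axis=0) - pr.mean(axis=0))[[10, 11]]
    assert np.allclose(diff, 0.5 ** 2 / 2.0, rtol=0.5)


def test_signal_energy_equals_sum_of_coefficient_powers(small_config):
    trial = generate_training_session(small_config, 0, 0)[0]
    _, p = dft_coefficient_powers(trial.signal, small_config.sampling_rate)
    total = p[..., 1:].sum(axis=-1)  # drop DC -> population variance
    var = trial.signal.var(axis=-1)
    assert np.allclose(total, var, rtol=1e-6)


def test_fisher_separability_monotone_in_amplitude():
    """Population Fisher score of the planted band-power feature grows
    strictly with effect amplitude (large-sample estimate)."""
    cfg = GeneratorConfig(n_participants=1, seed=5)
    rng = _rng(cfg, 9, 9, 9)
    js = []
    n = 400
    for amp in (0.15, 0.3, 0.6):
        sig_a = _synthesize_signals(cfg, rng, np.full(n, amp))
        sig_r = _synthesize_signals(cfg, rng, np.zeros(n))
        ch = cfg.active_channels[0]
        fa = np.stack([band_powers(s[ch], cfg.sampling_rate)[10] for s in sig_a])
        fr = np.stack([band_powers(s[ch], cfg.sampling_rate)[10] for s in sig_r])
        j = (fa.mean() - fr.mean()) ** 2 / (fa.var() + fr.var())
        js.append(j)
    assert js[0] < js[1] < js[2]


def test_protocol_mode_respects_session_time_budget():
    """With a 50-min cap, intersections stop once their cumulative time
    (K x (5-s period + 5-s break) + 10 s overhead) exceeds the budget."""
    cfg = GeneratorConfig(n_participants=1, intersections_per_session=200,
                          session_time_limit_min=50.0, seed=3)
    inters = generate_online_session(cfg, 0, 0)
    assert 0 < len(inters) < 200
    seconds = sum(it.n_directions * 10.0 + 10.0 for it in inters)
    assert seconds <= 50.0 * 60.0
    with pytest.raises(ValueError, match="time limit"):
        generate_online_session(GeneratorConfig(
            n_participants=1, session_time_limit_min=0.1, seed=3), 0, 0)


def test_response_surfaces_bounded_and_serializable():
    for surf in (ConstantSurface(1.2),
                 GaussianBumpSurface(center=(0.6, 0.4)),
                 LinearSurface(state="attention")):
        grid = np.linspace(0, 1, 5)
        vals = [surf(f, fr, a) for f in grid for fr in grid for a in grid]
        assert all(0.0 <= v <= 2.0 for v in vals)
        again = surface_from_dict(surf.to_dict())
        assert again == surf


def test_config_validation_and_yaml_roundtrip(tmp_path):
    with pytest.raises(ValueError):
        GeneratorConfig(n_participants=0)
    with pytest.raises(ValueError):
        GeneratorConfig(sampling_rate=-1)
    with pytest.raises(ValueError):
        GeneratorConfig(base_band=(30.0, 10.0))
    cfg = GeneratorConfig(n_participants=3, seed=42,
                          response_surface=GaussianBumpSurface())
    path = tmp_path / "cfg.yaml"
    cfg.to_yaml(path)
    back = GeneratorConfig.from_yaml(path)
    assert back == cfg
    # seed is mandatory in config files
    bad = tmp_path / "bad.yaml"
    bad.write_text("n_participants: 2\n")
    with pytest.raises(ValueError, match="seed"):
        GeneratorConfig.from_yaml(bad)
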