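"""Generator calibration, determinism and analytic limits."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from habclust.embedding import extract_feature_tables, select_k
from habclust.event_modulation import compute_fsmi, compute_psth
from habclust.features import compute_scalar_features
from habclust.io_formats import RunConfig
from habclust.synthetic import (
    PHENOTYPE_TARGETS,
    ResponseSpec,
    StateSpec,
    TypeSpec,
    calibrate_type_spec,
    generate_fs_session,
    generate_population,
    generate_spike_train,
    generate_state_session,
    preset_specs,
)
from habclust.state_modulation import compute_bsmi, partition_states


def test_same_seed_reproduces_spike_times_exactly():
    spec = calibrate_type_spec(1, 5.0, 1.2, 0.15)
    a = generate_spike_train(spec, 60.0, seed=42)
    b = generate_spike_train(spec, 60.0, seed=42)
    np.testing.assert_array_equal(a.spike_times, b.spike_times)
    c = generate_spike_train(spec, 60.0, seed=43)
    assert not np.array_equal(a.spike_times, c.spike_times)


def test_regular_limit_low_cv_no_bursts():
    """Tiny target CV and no bursts give a near-clock train."""
    spec = TypeSpec(type_id=1, target_rate=10.0, target_cv=0.01)
    f = compute_scalar_features(generate_spike_train(spec, 120.0, seed=0))
    assert f.cv < 0.05
    assert f.burst_index == 0.0
    assert f.rate == pytest.approx(10.0, rel=0.05)


def test_poisson_limit_unit_cv():
    """Unit target CV and no refractoriness reduce to a Poisson process."""
    spec = TypeSpec(type_id=1, target_rate=5.0, target_cv=1.0)
    f = compute_scalar_features(generate_spike_train(spec, 2000.0, seed=1))
    assert f.cv == pytest.approx(1.0, abs=0.05)


@pytest.mark.parametrize("condition", ["anesthetized", "awake"])
def test_presets_recover_published_statistics(condition):
    """Population means of rate/CV/burst match the published per-type
    values within +/-30% over 20 seeds for every phenotype."""
    for spec in preset_specs(condition):
        target = np.array(PHENOTYPE_TARGETS[condition][spec.type_id])
        measured = []
        for s in range(20):
            f = compute_scalar_features(
                generate_spike_train(spec, 120.0, seed=9000 + 100 * spec.type_id + s)
            )
            measured.append([f.rate, f.cv, f.burst_index])
        mean = np.mean(measured, axis=0)
        # the Type-2 burst target is ~0.004; allow the same 30% relative
        # band with a small absolute floor so it is not vacuous noise
        np.testing.assert_allclose(mean, target, rtol=0.30, atol=0.002)


def test_preset_rates_ordered_by_type():
    """Measured mean rates ascend Type-1 < Type-2 < Type-3 < Type-4."""
    specs = preset_specs("anesthetized")
    dataset, labels = generate_population(specs, n_per_type=20, duration=120.0, seed=3)
    rates = {tid: [] for tid in (1, 2, 3, 4)}
    for train, lab in zip(dataset.trains, labels):
        rates[lab].append(train.n_spikes / train.duration)
    means = [np.mean(rates[t]) for t in (1, 2, 3, 4)]
    assert means == sorted(means)


def test_population_counts_and_label_alignment():
    specs = preset_specs("anesthetized")
    dataset, labels = generate_population(specs, n_per_type=5, duration=30.0, seed=0)
    assert len(dataset) == 20
    assert sorted(np.bincount(labels)[1:]) == [5, 5, 5, 5]
    # labels follow the shuffle: the id prefix encodes the true type
    for train, lab in zip(dataset.trains, labels):
        assert train.neuron_id.startswith(f"t{lab}_")
    with pytest.raises(ValueError):
        generate_population(specs[:1], 5, 30.0, 0)
    with pytest.raises(ValueError):
        generate_population(specs, 0, 30.0, 0)


def test_identical_specs_cluster_at_chance():
    """Two 'types' with the same spec are unrecoverable: ARI stays near 0."""
    spec = calibrate_type_spec(1, 6.0, 1.0, 0.1)
    twin = calibrate_type_spec(2, 6.0, 1.0, 0.1)
    dataset, labels = generate_population([spec, twin], 30, 90.0, seed=5)
    (table,) = extract_feature_tables([dataset.trains], RunConfig(seed=5))
    model = select_k(table, k_grid=(2,), n_restarts=10, seed=5)
    assert abs(adjusted_rand_score(labels, model.labels)) < 0.1


def test_fs_session_none_kind_flat_psth():
    resp = ResponseSpec(kind="none", n_trials=500)
    train, trials = generate_fs_session(10.0, resp, seed=0)
    rec = compute_fsmi(train, trials)
    assert abs(rec.fsmi) < 0.03
    psth = compute_psth(train, trials)
    assert psth.rate.mean() == pytest.approx(10.0, rel=0.05)
    assert psth.rate.std() < 2.0


def test_fs_session_window_gain_hits_fsmi_identity():
    """Stimulus-window gain g yields FSMI -> (g-1)/(g+1)."""
    resp = ResponseSpec.from_window_gain(3.0, n_trials=300)
    train, trials = generate_fs_session(10.0, resp, seed=4)
    assert compute_fsmi(train, trials).fsmi == pytest.approx(0.5, abs=0.05)


def test_fs_session_full_inhibition_reaches_minus_one():
    resp = ResponseSpec(kind="inhibited", inhibited_factor=0.0, n_trials=150)
    train, trials = generate_fs_session(8.0, resp, seed=6)
    assert compute_fsmi(train, trials).fsmi == pytest.approx(-1.0)


def test_state_session_bsmi_identity_and_null():
    """Planted gain g yields BSMI -> (g-1)/(g+1); gain 1 yields ~0."""
    train, motion = generate_state_session(
        StateSpec(active_gain=2.0, session_length=600.0), 10.0, seed=2
    )
    rec = compute_bsmi(train, partition_states(motion))
    assert rec.bsmi == pytest.approx(1.0 / 3.0, abs=0.05)

    train0, motion0 = generate_state_session(
        StateSpec(active_gain=1.0, session_length=600.0), 10.0, seed=2
    )
    rec0 = compute_bsmi(train0, partition_states(motion0))
    assert abs(rec0.bsmi) < 0.05


def test_spec_validation_rejects_nonphysical_values():
    with pytest.raises(ValueError):
        TypeSpec(type_id=1, target_rate=-1.0, target_cv=1.0)
    with pytest.raises(ValueError):
        TypeSpec(type_id=1, target_rate=5.0, target_cv=1.0, burst_prob=1.5)
    with pytest.raises(ValueError):
        TypeSpec(type_id=1, target_rate=5.0, target_cv=1.0,
                 intra_burst_isi=(0.01, 0.03))
    with pytest.raises(ValueError):
        ResponseSpec(kind="excited", gains=(-1.0, 1.0))
    with pytest.raises(ValueError):
        StateSpec(active_gain=0.0)
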