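"""Preprocessing chain: unwrapping, pulse regression, QC, epoching, scaling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from erosdecode import (
    PreprocessConfig, ChannelRecord,
    unwrap_phase, regress_pulse, qc_channels, project_voxels,
    preprocess_block, scale_maxabs,
)

CFG = PreprocessConfig()


# ---------------------------------------------------------------------------
# phase unwrapping
# ---------------------------------------------------------------------------

def test_unwrap_constant_unchanged():
    s = np.full(50, 17.0)
    np.testing.assert_allclose(unwrap_phase(s, 360.0), s)


def test_unwrap_single_wrap_restores_ramp():
    period = 360.0
    ramp = np.linspace(0, 300, 100)          # wraps once past +period/2
    wrapped = ((ramp + period / 2) % period) - period / 2
    out = unwrap_phase(wrapped, period)
    assert np.all(np.diff(out) > 0)
    np.testing.assert_allclose(out, ramp, atol=1e-9)


def test_unwrap_inverts_synthetic_wrapping(rng):
    """A smooth random series wrapped k times is recovered exactly."""
    period = 200.0
    orig = np.cumsum(rng.normal(0, 20, size=300))
    orig -= orig[0]                           # start inside the base interval
    wrapped = ((orig + period / 2) % period) - period / 2
    np.testing.assert_allclose(unwrap_phase(wrapped, period), orig, atol=1e-8)


def test_unwrap_rejects_nonfinite():
    with pytest.raises(ValueError):
        unwrap_phase(np.array([0.0, np.nan]), 360.0)


# ---------------------------------------------------------------------------
# pulse regression
# ---------------------------------------------------------------------------

def _ref(n=400):
    t = np.arange(n) / 39.0625
    return np.sin(2 * np.pi * 1.2 * t)


def test_regress_pulse_removes_collinear():
    ref = _ref()
    residual = regress_pulse(3.0 * ref, ref)
    assert np.abs(residual).max() < 1e-10


def test_regress_pulse_keeps_orthogonal():
    n = 400
    t = np.arange(n)
    ref = np.sin(2 * np.pi * 8 * t / n)
    sig = np.sin(2 * np.pi * 29 * t / n)      # orthogonal to ref and quadrature
    out = regress_pulse(sig, ref)
    np.testing.assert_allclose(out, sig, atol=1e-10)


def test_regress_pulse_recovers_signal():
    n = 400
    t = np.arange(n)
    ref = np.sin(2 * np.pi * 8 * t / n)
    sig = np.sin(2 * np.pi * 29 * t / n)
    out = regress_pulse(sig + 0.7 * ref, ref)
    np.testing.assert_allclose(out, sig, atol=1e-9)
    assert abs(np.corrcoef(out, ref)[0, 1]) < 1e-10


def test_regress_pulse_zero_variance_reference():
    with pytest.raises(ValueError):
        regress_pulse(np.ones(10), np.ones(10))


# ---------------------------------------------------------------------------
# channel QC
# ---------------------------------------------------------------------------

def _chan(dist, sd, ac):
    return ChannelRecord(np.zeros(4), dist, sd, ac)


def test_qc_examples():
    assert qc_channels([_chan(1.5, 100, 200)], CFG) == []      # too close
    kept = qc_channels([_chan(3.0, 150, 120)], CFG)
    assert len(kept) == 1


def test_qc_boundaries():
    assert len(qc_channels([_chan(2.0, 100, 200)], CFG)) == 1   # distance inclusive
    assert len(qc_channels([_chan(7.0, 100, 200)], CFG)) == 1
    assert qc_channels([_chan(3.0, 200.0, 200)], CFG) == []     # strictly < 200
    assert qc_channels([_chan(3.0, 100, 100.0)], CFG) == []     # strictly > 100


@settings(max_examples=60, deadline=None)
@given(st.lists(st.tuples(st.floats(0.5, 10), st.floats(0, 400), st.floats(0, 300)),
                min_size=0, max_size=30))
def test_qc_equals_brute_force_and_idempotent(records):
    chans = [_chan(d, s, a) for d, s, a in records]
    kept = qc_channels(chans, CFG)
    brute = [c for c in chans
             if 2.0 <= c.source_detector_distance <= 7.0
             and c.phase_sd < 200.0 and c.mean_ac > 100.0]
    assert kept == brute
    assert qc_channels(kept, CFG) == kept


# ---------------------------------------------------------------------------
# voxel projection
# ---------------------------------------------------------------------------

def test_project_single_channel(rng):
    s = rng.normal(size=20)
    ch = ChannelRecord(s, 3.0, 10, 200, voxel_targets=(2,))
    out, viable = project_voxels([ch], 5)
    np.testing.assert_allclose(out[2], s)
    assert viable.tolist() == [False, False, True, False, False]


def test_project_cancellation(rng):
    s = rng.normal(size=20)
    chans = [ChannelRecord(s, 3.0, 10, 200, voxel_targets=(0,)),
             ChannelRecord(-s, 3.0, 10, 200, voxel_targets=(0,))]
    out, _ = project_voxels(chans, 2)
    np.testing.assert_allclose(out[0], 0.0, atol=1e-12)


def test_project_matches_group_mean(rng):
    chans = [ChannelRecord(rng.normal(size=30), 3.0, 10, 200,
                           voxel_targets=(int(rng.integers(0, 5)),))
             for _ in range(12)]
    out, viable = project_voxels(chans, 5)
    for v in range(5):
        group = [c.series for c in chans if v in c.voxel_targets]
        if group:
            np.testing.assert_allclose(out[v], np.mean(group, axis=0))
        else:
            assert not viable[v]


# ---------------------------------------------------------------------------
# block pipeline
# ---------------------------------------------------------------------------

def test_epoch_shape_is_56_samples(rng):
    """716 ms either side of the response at 39.0625 Hz -> 56 samples."""
    assert CFG.n_epoch == 56
    block = rng.normal(size=(4, 400))
    epochs = preprocess_block(block, [100, 250], CFG)
    assert len(epochs) == 2
    assert all(e.data.shape == (4, 56) for e in epochs)


def test_constant_block_gives_zero_epochs():
    block = np.full((3, 400), 7.3)
    epochs = preprocess_block(block, [200], CFG)
    np.testing.assert_allclose(epochs[0].data, 0.0, atol=1e-9)


def test_slow_drift_attenuated(rng):
    """A 0.05 Hz component sits below the 0.1 Hz band edge."""
    t = np.arange(4000) / CFG.fs
    block = np.sin(2 * np.pi * 0.05 * t)[None, :]
    from scipy.signal import sosfiltfilt
    out = sosfiltfilt(CFG.sos(), block - block.mean(), axis=1)
    assert np.sqrt(np.mean(out**2)) < 0.1 * np.sqrt(np.mean(block**2))


def test_baseline_window_mean_is_zero(rng):
    """Per-voxel mean over the 998 ms pre-response window vanishes."""
    block = rng.normal(size=(5, 500))
    e = 250
    nb = CFG.n_baseline
    assert nb == 39
    from scipy.signal import sosfiltfilt
    centered = block - block.mean(axis=1, keepdims=True)
    filtered = sosfiltfilt(CFG.sos(), centered, axis=1)
    wide = filtered[:, e - nb:e + CFG.n_crop_half]
    corrected = wide - wide[:, :nb].mean(axis=1, keepdims=True)
    assert np.abs(corrected[:, :nb].mean(axis=1)).max() < 1e-9
    # and the cropped epoch from the public API matches the last 56 columns
    ep = preprocess_block(block, [e], CFG)[0]
    np.testing.assert_allclose(ep.data, corrected[:, nb - CFG.n_crop_half:], atol=1e-12)


def test_bandpass_is_zero_phase():
    """Filtering a symmetric pulse keeps it symmetric."""
    n = 8001        # long enough for the 0.1 Hz corner's transient to die out
    t = np.arange(n) - n // 2
    pulse = np.exp(-t**2 / (2 * 15.0**2))[None, :]
    from scipy.signal import sosfiltfilt
    out = sosfiltfilt(CFG.sos(), pulse, axis=1)[0]
    asym = np.abs(out - out[::-1]).max()
    assert asym < 1e-6 * np.abs(out).max()


def test_edge_events_skipped(rng, caplog):
    block = rng.normal(size=(3, 200))
    with caplog.at_level("WARNING"):
        epochs = preprocess_block(block, [5, 100], CFG)
    assert len(epochs) == 1
    assert any("skipped" in r.message for r in caplog.records)


def test_band_validation():
    with pytest.raises(ValueError):
        PreprocessConfig(band=(12.0, 0.1))
    with pytest.raises(ValueError):
        PreprocessConfig(band=(0.1, 30.0))   # above Nyquist at 39.0625 Hz


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------

def test_scale_maxabs_unit_peak(rng):
    ep = rng.normal(size=(4, 8)) * 4.0
    out = scale_maxabs(ep)
    assert np.abs(out).max() == pytest.approx(1.0)


def test_scale_maxabs_zero_epoch():
    ep = np.zeros((3, 5))
    np.testing.assert_array_equal(scale_maxabs(ep), ep)


def test_scale_maxabs_preserves_structure(rng):
    ep = rng.normal(size=(6, 10))
    out = scale_maxabs(ep)
    assert np.unravel_index(np.abs(out).argmax(), out.shape) == \
        np.unravel_index(np.abs(ep).argmax(), ep.shape)
    nz = ep != 0
    np.testing.assert_allclose(out[nz] / ep[nz], 1.0 / np.abs(ep).max())
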