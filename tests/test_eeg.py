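import numpy as np
import pytest

from pulsedetect.eeg import (
    EpochSet,
    epoch_and_clean,
    gratton_correct,
    synthetic_recording,
)

SFREQ = 500.0


def simple_recording(n_ch=2, n_events=10, amp=0.0):
    """Quiet recording with optional per-event spikes."""
    iti = int(2 * SFREQ)
    n = (n_events + 4) * iti
    cont = np.zeros((n_ch, n))
    events = (np.arange(n_events) + 2) * iti
    return cont, events


class TestEpochAndClean:
    def test_flat_recording_nothing_rejected(self):
        cont, events = simple_recording()
        epochs, _ = epoch_and_clean(cont, events, SFREQ)
        assert epochs.good.all()
        assert np.allclose(epochs.data, 0.0)

    def test_epoch_window_and_times(self):
        cont, events = simple_recording()
        epochs, _ = epoch_and_clean(cont, events, SFREQ)
        assert epochs.times[0] == pytest.approx(-800.0)
        assert epochs.times[-1] == pytest.approx(1000.0 - 1000.0 / SFREQ)
        assert epochs.data.shape == (10, 2, int(1.8 * SFREQ))

    def test_amplitude_rejection_stages(self):
        cont, events = simple_recording()
        # trial 2: raw 1500 uV spike -> first-stage rejection
        cont[0, events[2] + 10] = 1500.0
        # trial 5: 700 uV spike -> survives stage 1, rejected at stage 2
        cont[1, events[5] + 20] = 700.0
        epochs, _ = epoch_and_clean(cont, events, SFREQ)
        assert epochs.rejected[2] == "amplitude_1000"
        assert epochs.rejected[5] == "amplitude_500"
        assert epochs.good.sum() == 8

    def test_rejection_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        cont, events = simple_recording()
        cont += rng.normal(0, 200, size=cont.shape)
        n_rej = []
        for r2 in (300.0, 500.0, 800.0):
            ep, _ = epoch_and_clean(cont, events, SFREQ, reject2=r2)
            n_rej.append((~ep.good).sum())
        assert n_rej[0] >= n_rej[1] >= n_rej[2]

    def test_edge_events_flagged_not_raised(self):
        cont, events = simple_recording()
        events = np.concatenate([[5], events])  # too close to start
        epochs, _ = epoch_and_clean(cont, events, SFREQ)
        assert epochs.rejected[0] == "edge"
        assert epochs.good.sum() == 10

    def test_baseline_mean_is_zero(self):
        rng = np.random.default_rng(1)
        cont, events = simple_recording()
        cont += rng.normal(50, 30, size=cont.shape)
        epochs, _ = epoch_and_clean(cont, events, SFREQ)
        m = (epochs.times >= -300) & (epochs.times < 0)
        base = epochs.data[:, :, m].mean(axis=2)
        assert np.abs(base).max() < 1e-9

    def test_full_chain_recovers_clean_signal(self):
        """Blink-contaminated alpha recording: post-correction RMS error
        is under 5% of the signal RMS."""
        cont, eog, events, truth = synthetic_recording(
            n_channels=3, n_events=40, sfreq=SFREQ, noise_amp=0.0,
            propagation=0.35, seed=2,
        )
        epochs, coeffs = epoch_and_clean(cont, events, SFREQ, eog=eog)
        clean_ep, _ = epoch_and_clean(truth["clean"], events, SFREQ)
        good = epochs.good
        err = epochs.data[good] - clean_ep.data[good]
        rms_err = np.sqrt(np.mean(err**2))
        rms_sig = np.sqrt(np.mean(clean_ep.data[good] ** 2))
        assert rms_err < 0.05 * rms_sig


class TestGratton:
    def _epochs(self, data):
        n_t, n_c, n_s = data.shape
        return EpochSet(data, np.arange(n_s) * 2.0, [f"ch{i}" for i in range(n_c)],
                        SFREQ, np.array([""] * n_t, dtype=object))

    def test_exact_linear_contamination(self):
        rng = np.random.default_rng(3)
        eog = np.zeros((20, 2, 100))
        eog[:, 0] = rng.normal(0, 50, (20, 100))
        eeg = 2.0 * eog[:, [0]]  # single channel = 2 x vertical EOG
        out, coeffs = gratton_correct(self._epochs(eeg), eog)
        assert coeffs[0, 0] == pytest.approx(2.0, abs=1e-9)
        assert np.abs(out.data).max() < 1e-9

    def test_orthogonal_noise_unchanged(self):
        rng = np.random.default_rng(4)
        eeg = rng.normal(0, 10, (50, 2, 200))
        eog = rng.normal(0, 50, (50, 2, 200))
        out, coeffs = gratton_correct(self._epochs(eeg), eog)
        assert np.abs(coeffs).max() < 0.02
        assert np.allclose(out.data, eeg, atol=1.5)

    def test_recovers_injected_propagation_factor(self):
        """b = 0.35 recovered within +/- 0.02 from a 100-trial fixture."""
        cont, eog, events, truth = synthetic_recording(
            n_channels=2, n_events=100, sfreq=SFREQ, propagation=0.35, seed=5,
        )
        _, coeffs = epoch_and_clean(cont, events, SFREQ, eog=eog)
        assert coeffs[:, 0] == pytest.approx(0.35, abs=0.02)

    def test_correction_reduces_heldout_eog_variance(self):
        """On a held-out half, EOG-explainable EEG variance drops."""
        cont, eog, events, _ = synthetic_recording(
            n_channels=2, n_events=60, sfreq=SFREQ, propagation=0.5, seed=6,
        )
        i0, i1 = -int(0.8 * SFREQ), int(1.0 * SFREQ)
        eeg_ep = np.stack([cont[:, e + i0:e + i1] for e in events])
        eog_ep = np.stack([eog[:, e + i0:e + i1] for e in events])
        train, test = slice(0, 30), slice(30, 60)
        ep_train = self._epochs(eeg_ep[train])
        _, coeffs = gratton_correct(ep_train, eog_ep[train])
        corrected_test = eeg_ep[test] - np.einsum(
            "ce,tes->tcs", coeffs, eog_ep[test]
        )

        def eog_r2(Y, X):
            x = X.transpose(1, 0, 2).reshape(2, -1).T
            y = Y.transpose(1, 0, 2).reshape(Y.shape[1], -1).T
            beta, *_ = np.linalg.lstsq(x, y, rcond=None)
            resid = y - x @ beta
            return 1 - resid.var() / y.var()

        before = eog_r2(eeg_ep[test], eog_ep[test])
        after = eog_r2(corrected_test, eog_ep[test])
        assert after < before

    def test_zero_eog_variance_rejected(self):
        eeg = np.random.default_rng(7).normal(0, 1, (10, 2, 50))
        with pytest.raises(ValueError, match="variance"):
            gratton_correct(self._epochs(eeg), np.zeros((10, 2, 50)))
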