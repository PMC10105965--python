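import numpy as np
import pytest

from septodg import synthetic_data as synth


@pytest.fixture
def base_cfg():
    return synth.SimConfig(seed=0)


@pytest.fixture
def quiet_photometry_cfg():
    """No events, no drift, no motion, no noise."""
    return synth.SimConfig(
        seed=0,
        genotype_params={"WT": synth.GenotypeParams(event_rate_per_min=0.0)},
        photometry=synth.PhotometryParams(
            duration_s=60.0, drift_amplitude=0.0, motion_amplitude=0.0, noise_sd=0.0
        ),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def match_events(true_times: np.ndarray, det_times: np.ndarray, tol_s: float) -> tuple[int, int, int]:
    """Greedy event matching: (true positives, false positives, false negatives)."""
    true = list(true_times)
    tp = 0
    for t in det_times:
        if true and min(abs(np.asarray(true) - t)) <= tol_s:
            i = int(np.argmin(abs(np.asarray(true) - t)))
            true.pop(i)
            tp += 1
    fp = len(det_times) - tp
    fn = len(true)
    return tp, fp, fn


def f1_score(true_times, det_times, tol_s):
    tp, fp, fn = match_events(np.asarray(true_times), np.asarray(det_times), tol_s)
    if tp == 0:
        return 0.0
    prec = tp / (tp + fp)
    rec = tp / (tp + fn)
    return 2 * prec * rec / (prec + rec)
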