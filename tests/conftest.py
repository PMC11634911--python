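import numpy as np
import pytest

from phonolvp.cardiosim import (NoiseConfig, ProtocolSpec, ProtocolStep,
                                default_coupling, hfref_preset,
                                render_signals, simulate_hemodynamics)

FS = 1000.0
#: canonical seed used by the deterministic study fixtures
SEED = 0


def simulate_step(rate=None, duration=60.0, noise=None, seed=SEED,
                  preset=None, coupling=None):
    """One simulated pacing step with its ground truth."""
    preset = preset or hfref_preset()
    coupling = coupling or default_coupling(preset)
    label = "spontaneous" if rate is None else f"{rate:g}bpm"
    protocol = ProtocolSpec((ProtocolStep(label, rate, duration),))
    truth = simulate_hemodynamics(protocol, preset, coupling, seed)[0]
    record = render_signals(truth, FS, noise, seed=seed, coupling=coupling)
    return record, truth


def match_beats(seg_or_times, truth, fs=FS, tol=0.02):
    """Pair detected beat onsets (seconds) with truth beat indices."""
    onsets = np.asarray(seg_or_times, float)
    pairs = []
    for k, t0 in enumerate(onsets):
        j = int(np.argmin(np.abs(truth.r_times[:-1] - t0)))
        if abs(truth.r_times[j] - t0) <= tol:
            pairs.append((k, j))
    return pairs


@pytest.fixture(scope="session")
def hfref_step_nf():
    """Noise-free spontaneous HFrEF step (60 s) with ground truth."""
    return simulate_step(rate=None, duration=60.0, noise=None)


@pytest.fixture(scope="session")
def hfref_step_nf_segmented(hfref_step_nf):
    from phonolvp.preprocess_segment import segment_record
    record, truth = hfref_step_nf
    seg, med = segment_record(record)
    return record, truth, seg, med


@pytest.fixture(scope="session")
def hfref_spont_long_nf():
    """Noise-free spontaneous HFrEF step at full study length (180 s)."""
    return simulate_step(rate=None, duration=180.0, noise=None)


@pytest.fixture(scope="session")
def hfref_spont_long_20db():
    """Spontaneous HFrEF step (180 s) at 20 dB SNR on the non-invasive
    channels."""
    return simulate_step(rate=None, duration=180.0,
                         noise=NoiseConfig.noninvasive(20.0))


@pytest.fixture(scope="session")
def hfref_study_results():
    """Full default HFrEF pipeline run (5 steps, 20 dB SNR, seed 0)."""
    from phonolvp.regression_eval import evaluate_step
    from phonolvp.cardiosim import default_protocol, simulate_study

    pairs = simulate_study(default_protocol(step_duration=60.0), "hfref",
                           noise=NoiseConfig.noninvasive(20.0), seed=SEED)
    evaluations = [evaluate_step(rec, truth.step_label) for rec, truth in pairs]
    return pairs, evaluations
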