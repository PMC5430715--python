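import numpy as np
import pytest

from ambifocal import (
    ClassificationConfig,
    ClassifiedTrial,
    DetectionConfig,
    ModelParams,
    RenderConfig,
    classify_fixations,
    classify_saccades,
    detect_events,
    generate_layout,
    generate_trial_events,
    render_gaze_trace,
)

#: sampling rate used for rendered-trace tests; the detector scales its
#: filters in time so results are equivalent to the native 20 kHz.
TEST_FS = 2000.0


@pytest.fixture(scope="session")
def layout5():
    return generate_layout(n_objects=5, seed=7, center_object=True)


@pytest.fixture(scope="session")
def standard_params():
    return ModelParams(
        p_sw=0.2, p_intra_e=0.1, p_trans_e=0.9, p_intra_l=0.9, p_trans_l=0.55,
        p_bg=0.2, n_fix=12, initial_condition="object",
    )


@pytest.fixture(scope="session")
def rendered_suite(layout5, standard_params):
    """Noise-free rendered trials with ground truth, detection and labels."""
    rng = np.random.default_rng(123)
    cfg = RenderConfig(sampling_rate=TEST_FS, position_noise_sd=0.0)
    suite = []
    for trial_id in range(1, 31):
        truth = generate_trial_events(standard_params, layout5, seed=rng)
        trace = render_gaze_trace(truth, cfg, seed=rng)
        saccades, fixations = detect_events(trace, DetectionConfig())
        labeled = classify_fixations(fixations, layout5, ClassificationConfig())
        typed = classify_saccades(labeled, saccades)
        suite.append(
            {
                "truth": truth,
                "trace": trace,
                "trial": ClassifiedTrial(
                    trial_id=trial_id,
                    stimulus_onset=trace.stimulus_onset,
                    fixations=labeled,
                    saccades=typed,
                ),
            }
        )
    return suite
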