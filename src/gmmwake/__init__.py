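"""gmmwake: behavioral model and evaluation pipeline for a nanopower
analog Gaussian-mixture wake-up classifier for EEG seizure prediction.

The package covers the full chain of the system it models: 4-D band-power
feature extraction from single-channel EEG, per-class diagonal-covariance
GMM training by EM, maximum-likelihood classification, an equation-level
model of the analog realization (subthreshold bump cascades summed per
class and compared by a winner-take-all stage), alarm-based
sensitivity/specificity scoring around labeled seizures, device-mismatch
Monte-Carlo analysis, and parameter/operation/power accounting.
"""

from .gmm import (
    ArchitectureSpec,
    ClassGMM,
    GaussianComponent,
    GMMClassifier,
    classify,
    classify_batch,
    component_pdf,
    count_operations,
    count_parameters,
    fit_em,
    gaussian_pdf,
    load_classifier,
    mixture_pdf,
    save_classifier,
)
from .analog import (
    AnalogClassifierConfig,
    BumpParams,
    DeviceModel,
    FeatureScaler,
    MismatchSpec,
    apply_mismatch,
    bump_current,
    calibrate_width,
    class_current,
    classify_analog,
    classify_analog_batch,
    map_gmm_to_analog,
    monte_carlo_eval,
    multivariate_bump,
    wta,
)
from .features import BandSpec, FeatureVector, SignalWindow, extract_features, make_windows
from .evaluate import (
    EvalReport,
    SeizureTimeline,
    alarms_from_predictions,
    evaluate_alarms,
    label_timeline,
    sensitivity,
    specificity,
    system_power,
)
from .simulate import (
    EEGSimSpec,
    StateProfile,
    default_truth,
    generate_eeg,
    generate_features,
    generate_timeline,
    generate_window_features,
)
from .pipeline import (
    CLASS_LABELS,
    PowerConstants,
    accounting_report,
    evaluate_windows,
    predict_windows,
    train_classifier,
    train_test_split_windows,
)

__version__ = "0.1.0"
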