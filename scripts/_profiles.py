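"""Helper for the reproduction script: a response profile from fixed means."""

import numpy as np

from whiskmap.data_model import AnalysisConfig
from whiskmap.responsiveness import WHISKER_LABELS, ResponseProfile


def profile_from_means(means: np.ndarray) -> ResponseProfile:
    means = np.asarray(means, dtype=float)
    significant = means != 0
    return ResponseProfile(
        roi_id="worked-example",
        whiskers=WHISKER_LABELS,
        mean=means,
        p=np.where(significant, 0.001, 0.5),
        sign=np.where(means >= 0, 1, -1),
        significant=significant,
        blank_mean=0.0,
        blank_sd=0.05,
        n_trials=np.full(9, 40),
        n_blank=100,
        single_trial_fraction=np.zeros(9),
        config=AnalysisConfig(),
    )
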