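"""Shared fixtures and independent oracles for the test suite."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from whiskmap.data_model import AnalysisConfig, TrialTable
from whiskmap.responsiveness import WHISKER_LABELS, ResponseProfile


def exact_perm_p(a, b, alternative="greater"):
    """Exhaustive-enumeration permutation p-value (independent oracle).

    Enumerates every split of the pooled trials into groups of the original
    sizes and counts splits whose mean difference is at least as extreme as
    the observed one (the identity split counts itself, as in the add-one
    Monte-Carlo convention's limit).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n = a.size
    obs = a.mean() - b.mean()
    idxs = list(range(pooled.size))
    k = tot = 0
    for c in combinations(idxs, n):
        sel = np.zeros(pooled.size, bool)
        sel[list(c)] = True
        d = pooled[sel].mean() - pooled[~sel].mean()
        tot += 1
        if alternative == "greater":
            k += d >= obs - 1e-12
        elif alternative == "less":
            k += d <= obs + 1e-12
        else:
            k += abs(d) >= abs(obs) - 1e-12
    return k / tot


def make_profile(means, significant=None, signs=None, blank_mean=0.0,
                 blank_sd=0.1, n_trials=20, config=None):
    """Hand-built ResponseProfile for unit tests (9 whisker means in C1..E3 order)."""
    means = np.asarray(means, float)
    if significant is None:
        significant = means > 0
    significant = np.asarray(significant, bool)
    if signs is None:
        signs = np.where(means >= 0, 1, -1)
    return ResponseProfile(
        roi_id="test",
        whiskers=WHISKER_LABELS,
        mean=means,
        p=np.where(significant, 0.001, 0.5),
        sign=np.asarray(signs, int),
        significant=significant,
        blank_mean=blank_mean,
        blank_sd=blank_sd,
        n_trials=np.full(9, n_trials),
        n_blank=50,
        single_trial_fraction=np.zeros(9),
        config=config or AnalysisConfig(n_permutations=500),
    )


def make_table(rows, roi_values, config=None):
    """TrialTable from (kind, whisker, lick) rows and an {roi: values} dict."""
    trials = pd.DataFrame(
        [
            {
                "session_id": "S0",
                "trial_index": i,
                "stimulus_kind": kind,
                "whisker": whisker,
                "lick": lick,
            }
            for i, (kind, whisker, lick) in enumerate(rows)
        ]
    )
    trials["whisker"] = trials["whisker"].astype("string")
    dff = pd.DataFrame(roi_values)
    return TrialTable(trials=trials, dff=dff,
                      config=config or AnalysisConfig())


@pytest.fixture(scope="session")
def fast_config():
    return AnalysisConfig(n_permutations=500, n_bootstrap=500,
                          subsample_reps=200, seed=7)


@pytest.fixture(scope="session")
def small_experiment():
    """One cached small two-session synthetic experiment."""
    from whiskmap.synthetic import SimulationConfig, simulate_experiment

    cfg = SimulationConfig(cells_per_column=12, n_sessions=2, seed=11)
    return simulate_experiment(cfg)
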