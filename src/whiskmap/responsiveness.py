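"""Evoked responses and per-cell, per-whisker response significance.

For each cell, the evoked ΔF/F of every single-whisker stimulus is compared
to blank trials with a Monte-Carlo permutation test (difference of means,
trials shuffled between the whisker and blank sets). Positive and negative
responses are two one-sided tests pooled into one p-value per stimulus (the
smaller tail, with its sign recorded); Benjamini–Hochberg FDR is applied per
cell across its single-whisker stimuli. A cell is whisker-responsive if at
least one whisker has a significant positive response; cells with only
significant negative responses are classed negative-only and excluded from
receptive-field analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._permutation import mc_p, null_mean_diffs, permutation_indicator
from .data_model import ALL_WHISKERS, AnalysisConfig, AnalysisError, TrialTable

__all__ = [
    "ResponseProfile",
    "compute_evoked",
    "permutation_response_test",
    "fdr_correct",
    "classify_responsiveness",
    "single_trial_responsive",
    "compute_response_profiles",
    "profiles_to_frame",
]

WHISKER_LABELS = tuple(w.label for w in ALL_WHISKERS)


def compute_evoked(trace: np.ndarray, onset: int, frame_rate: float,
                   config: AnalysisConfig | None = None) -> float:
    """Mean ΔF/F over the post-stimulus response window minus mean baseline.

    Windows are taken from ``config`` (defaults: response 0–1000 ms after
    onset, baseline 0–500 ms before onset). A frame is included when its
    acquisition interval overlaps the window, so the frame range is
    ``[floor(start), ceil(end))`` in frame units.
    """
    config = config or AnalysisConfig()
    trace = np.asarray(trace, dtype=float)
    t0, t1 = (t / 1000.0 for t in config.evoked_window_ms)
    b0, b1 = (t / 1000.0 for t in config.baseline_window_ms)
    r_lo = math.floor(onset + t0 * frame_rate)
    r_hi = math.ceil(onset + t1 * frame_rate)
    b_lo = math.floor(onset - b1 * frame_rate)
    b_hi = math.ceil(onset - b0 * frame_rate)
    if b_lo < 0 or r_hi > trace.size:
        raise ValueError(
            f"trace of {trace.size} frames does not cover baseline+response "
            f"windows [{b_lo}, {r_hi}) at onset {onset}"
        )
    return float(trace[r_lo:r_hi].mean() - trace[b_lo:b_hi].mean())


def evoked_from_traces(traces: np.ndarray, onset: int, frame_rate: float,
                       config: AnalysisConfig | None = None) -> np.ndarray:
    """Per-trial evoked ΔF/F from frame-resolved traces (trials × frames)."""
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    return np.array([
        compute_evoked(t, onset, frame_rate, config) for t in traces
    ])


@dataclass
class PermutationResult:
    observed: float
    p_positive: float
    p_negative: float

    @property
    def p(self) -> float:
        """Pooled per-stimulus p: the smaller one-sided tail."""
        return min(self.p_positive, self.p_negative)

    @property
    def sign(self) -> int:
        return 1 if self.p_positive <= self.p_negative else -1


def permutation_response_test(whisker_trials, blank_trials,
                              n_permutations: int = 10_000,
                              rng: np.random.Generator | None = None,
                              seed: int | None = None) -> PermutationResult:
    """Whisker-vs-blank permutation test on single-trial evoked ΔF/F.

    Returns the observed mean difference with one-sided Monte-Carlo p-values
    for positive (null ≥ observed) and negative (null ≤ observed) responses,
    add-one convention.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    a = np.asarray(whisker_trials, dtype=float)
    b = np.asarray(blank_trials, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("whisker and blank trial sets must be non-empty")
    if rng is None:
        rng = np.random.default_rng(seed)
    observed = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    ind = permutation_indicator(a.size, pooled.size, n_permutations, rng)
    null = null_mean_diffs(pooled, a.size, ind)
    return PermutationResult(
        observed=float(observed),
        p_positive=float(mc_p(null, observed, "greater")),
        p_negative=float(mc_p(null, observed, "less")),
    )


def fdr_correct(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up significance flags at FDR q."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def single_trial_responsive(evoked: float, blank_mean: float,
                            blank_sd: float) -> bool:
    """True iff a single trial's evoked ΔF/F strictly exceeds blank mean + SD."""
    if blank_sd < 0:
        raise ValueError("blank_sd must be >= 0")
    return evoked > blank_mean + blank_sd


@dataclass
class ResponseProfile:
    """Per-cell whisker response summary: means, significance, blank stats."""

    roi_id: str
    whiskers: tuple[str, ...]
    mean: np.ndarray                 # per-whisker mean evoked ΔF/F (NaN if unsampled)
    p: np.ndarray                    # pooled per-whisker p (smaller tail)
    sign: np.ndarray                 # +1 positive tail smaller, −1 negative
    significant: np.ndarray          # after per-cell BH FDR
    blank_mean: float
    blank_sd: float                  # n−1 denominator
    n_trials: np.ndarray             # per-whisker trial counts
    n_blank: int
    single_trial_fraction: np.ndarray
    config: AnalysisConfig = field(default_factory=AnalysisConfig)

    @property
    def sampled(self) -> np.ndarray:
        return self.n_trials > 0

    @property
    def significant_positive(self) -> np.ndarray:
        return self.significant & (self.sign > 0)

    @property
    def significant_negative(self) -> np.ndarray:
        return self.significant & (self.sign < 0)

    @property
    def responsive(self) -> bool:
        return bool(self.significant_positive.any())

    @property
    def negative_only(self) -> bool:
        return bool(self.significant_negative.any()) and not self.responsive

    def whisker_index(self, label: str) -> int:
        return self.whiskers.index(label)


def classify_responsiveness(profile: ResponseProfile) -> str:
    """'responsive', 'negative_only' (excluded downstream) or 'non_responsive'."""
    if profile.responsive:
        return "responsive"
    if profile.negative_only:
        return "negative_only"
    return "non_responsive"


def compute_response_profiles(table: TrialTable,
                              config: AnalysisConfig | None = None,
                              rng: np.random.Generator | None = None,
                              ) -> dict[str, ResponseProfile]:
    """Permutation response tests + FDR for every ROI in a trial table.

    Lick and non-single-whisker trials must already be filtered
    (:func:`whiskmap.data_model.filter_analysis_trials`). The permutation
    indicator matrices are drawn once per whisker and shared across ROIs
    (they are independent of the data, so each p-value is marginally valid).
    """
    config = config or table.config
    if rng is None:
        rng = config.rng(101)
    masks = table.stimulus_masks()
    blank_mask = masks["blank"]
    if not blank_mask.any():
        raise AnalysisError("no blank trials; responsiveness null undefined")
    values = table.dff.to_numpy(dtype=float)
    roi_ids = table.roi_ids
    n_rois = len(roi_ids)
    blanks = values[blank_mask]
    blank_mean = blanks.mean(axis=0)
    blank_sd = blanks.std(axis=0, ddof=1)
    n_whisk = len(WHISKER_LABELS)

    mean = np.full((n_whisk, n_rois), np.nan)
    p_pos = np.full((n_whisk, n_rois), np.nan)
    p_neg = np.full((n_whisk, n_rois), np.nan)
    frac = np.full((n_whisk, n_rois), np.nan)
    n_trials = np.zeros(n_whisk, dtype=int)

    for wi, label in enumerate(WHISKER_LABELS):
        wmask = masks[label]
        n_w = int(wmask.sum())
        n_trials[wi] = n_w
        if n_w == 0:
            continue
        wvals = values[wmask]
        mean[wi] = wvals.mean(axis=0)
        observed = mean[wi] - blank_mean
        pooled = np.concatenate([wvals, blanks], axis=0)
        ind = permutation_indicator(n_w, pooled.shape[0], config.n_permutations, rng)
        null = null_mean_diffs(pooled, n_w, ind)
        p_pos[wi] = mc_p(null, observed, "greater")
        p_neg[wi] = mc_p(null, observed, "less")
        frac[wi] = (wvals > blank_mean + blank_sd).mean(axis=0)

    pooled_p = np.fmin(p_pos, p_neg)
    sign = np.where(p_pos <= p_neg, 1, -1)
    sampled = n_trials > 0

    profiles: dict[str, ResponseProfile] = {}
    for ri, roi_id in enumerate(roi_ids):
        significant = np.zeros(n_whisk, dtype=bool)
        if sampled.any():
            significant[sampled] = fdr_correct(pooled_p[sampled, ri], config.fdr_q)
        profiles[roi_id] = ResponseProfile(
            roi_id=roi_id,
            whiskers=WHISKER_LABELS,
            mean=mean[:, ri].copy(),
            p=pooled_p[:, ri].copy(),
            sign=sign[:, ri].copy(),
            significant=significant,
            blank_mean=float(blank_mean[ri]),
            blank_sd=float(blank_sd[ri]),
            n_trials=n_trials.copy(),
            n_blank=int(blank_mask.sum()),
            single_trial_fraction=frac[:, ri].copy(),
            config=config,
        )
    return profiles


def profiles_to_frame(profiles: dict[str, ResponseProfile]) -> pd.DataFrame:
    """Tidy per-ROI table (one row per ROI, per-whisker columns)."""
    rows = []
    for roi_id, pr in profiles.items():
        row = {
            "roi_id": roi_id,
            "responsive": pr.responsive,
            "negative_only": pr.negative_only,
            "class": classify_responsiveness(pr),
            "blank_mean": pr.blank_mean,
            "blank_sd": pr.blank_sd,
            "n_blank": pr.n_blank,
        }
        for wi, w in enumerate(pr.whiskers):
            row[f"mean_{w}"] = pr.mean[wi]
            row[f"p_{w}"] = pr.p[wi]
            row[f"sig_{w}"] = bool(pr.significant[wi])
            row[f"sign_{w}"] = int(pr.sign[wi])
            row[f"strf_{w}"] = pr.single_trial_fraction[wi]
        rows.append(row)
    return pd.DataFrame(rows)
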