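"""Per-cell whisker tuning statistics.

Best whisker (BW) and statistically equivalent best whiskers (eBW), tuning
sharpness, columnar-whisker dominance index (CWDI), CW preference, tuning
center of mass (CoM) on the 3×3 whisker grid, and rank-ordered tuning
curves. Negative per-whisker responses are retained in rank curves and CWDI
but zeroed for sharpness, CW preference and CoM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._permutation import mc_p, null_mean_diffs, permutation_indicator
from .data_model import ALL_WHISKERS, AnalysisConfig, WhiskerId
from .responsiveness import ResponseProfile

__all__ = [
    "TuningSummary",
    "find_bw_and_ebw",
    "tuning_sharpness",
    "cw_dominance_index",
    "cw_preference",
    "tuning_com",
    "classify_column_tuning",
    "rank_ordered_curves",
    "compute_tuning_summaries",
]

WHISKER_LABELS = tuple(w.label for w in ALL_WHISKERS)


class _IndicatorCache:
    """Per-run cache of permutation indicator matrices keyed by group sizes.

    Matrices are drawn independently of any data, so sharing one across
    same-shaped tests keeps every p-value marginally valid.
    """

    def __init__(self, rng: np.random.Generator, n_perm: int):
        self.rng = rng
        self.n_perm = n_perm
        self._cache: dict[tuple[int, int], np.ndarray] = {}

    def get(self, n_a: int, n_tot: int) -> np.ndarray:
        key = (n_a, n_tot)
        if key not in self._cache:
            self._cache[key] = permutation_indicator(
                n_a, n_tot, self.n_perm, self.rng
            )
        return self._cache[key]


def _pair_p(a: np.ndarray, b: np.ndarray, cache: _IndicatorCache,
            alternative: str) -> float:
    observed = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    ind = cache.get(a.size, pooled.size)
    null = null_mean_diffs(pooled, a.size, ind)
    return float(mc_p(null, observed, alternative))


def find_bw_and_ebw(profile: ResponseProfile,
                    trials: dict[str, np.ndarray],
                    config: AnalysisConfig | None = None,
                    rng: np.random.Generator | None = None,
                    cache: _IndicatorCache | None = None,
                    ) -> tuple[str, list[str]]:
    """Best whisker and the set of statistically equivalent best whiskers.

    The BW is the significant-positive whisker with the largest mean evoked
    ΔF/F (ties broken by smaller p, then fixed whisker order). A significant
    whisker joins the eBW set when a two-sided permutation difference-of-means
    test against the BW's trials fails to reject at alpha (uncorrected).
    """
    config = config or profile.config
    if not profile.responsive:
        raise ValueError(f"ROI {profile.roi_id} is not whisker-responsive")
    if cache is None:
        if rng is None:
            rng = config.rng(102)
        cache = _IndicatorCache(rng, config.n_permutations)
    cand = np.flatnonzero(profile.significant_positive)
    order = sorted(
        cand, key=lambda i: (-profile.mean[i], profile.p[i], i)
    )
    bw_i = order[0]
    bw = profile.whiskers[bw_i]
    ebw = [bw]
    for i in cand:
        if i == bw_i:
            continue
        label = profile.whiskers[i]
        p = _pair_p(
            np.asarray(trials[label], float),
            np.asarray(trials[bw], float),
            cache, "two-sided",
        )
        if p > config.alpha:
            ebw.append(label)
    return bw, sorted(ebw, key=WHISKER_LABELS.index)


def _zeroed(values: np.ndarray) -> np.ndarray:
    """Negative (and unsampled) mean responses replaced by zero."""
    return np.clip(np.nan_to_num(values, nan=0.0), 0.0, None)


def tuning_sharpness(profile: ResponseProfile, bw: str | None = None) -> float | None:
    """(R_BW − R_W)/(R_BW + R_W); negative non-BW means zeroed in R_W.

    Returns None when R_BW ≤ 0 (undefined).
    """
    means = profile.mean
    bw_i = profile.whisker_index(bw) if bw else int(np.nanargmax(means))
    r_bw = means[bw_i]
    if not np.isfinite(r_bw) or r_bw <= 0:
        return None
    others = np.delete(_zeroed(means), bw_i)
    r_w = others.mean()
    return float((r_bw - r_w) / (r_bw + r_w))


def cw_dominance_index(profile: ResponseProfile, column: WhiskerId) -> float | None:
    """(R_CW − strongest SW)/|R_CW + strongest SW| on raw (un-zeroed) means.

    1 for a cell responding exclusively to its columnar whisker, 0 for equal
    CW and strongest-SW responses; values >1 or <0 arise with negative SW or
    CW responses. None when the denominator is zero.
    """
    cw_i = profile.whisker_index(column.label)
    r_cw = profile.mean[cw_i]
    others = np.delete(profile.mean, cw_i)
    r_sw = np.nanmax(others)
    denom = abs(r_cw + r_sw)
    if denom == 0 or not np.isfinite(denom):
        return None
    return float((r_cw - r_sw) / denom)


def cw_preference(profile: ResponseProfile, column: WhiskerId) -> float | None:
    """(R_CW − R_W)/(R_CW + R_W) with negative non-CW means zeroed in R_W."""
    cw_i = profile.whisker_index(column.label)
    r_cw = profile.mean[cw_i]
    if not np.isfinite(r_cw):
        return None
    r_w = np.delete(_zeroed(profile.mean), cw_i).mean()
    denom = r_cw + r_w
    if denom <= 0:
        return None
    return float((r_cw - r_w) / denom)


def tuning_com(profile: ResponseProfile) -> tuple[float, float] | None:
    """Response-weighted centroid on the 3×3 grid, negatives zeroed.

    x is the arc axis (arc 1→0, 2→1, 3→2) and y the row axis (C=0, D=1,
    E=2), unit spacing. None when no whisker has a positive mean response.
    """
    return com_from_means(profile.mean)


def com_from_means(means: np.ndarray) -> tuple[float, float] | None:
    w = _zeroed(np.asarray(means, dtype=float))
    total = w.sum()
    if total <= 0:
        return None
    rows = np.array([wk.grid[0] for wk in ALL_WHISKERS], dtype=float)
    arcs = np.array([wk.grid[1] for wk in ALL_WHISKERS], dtype=float)
    return (float((arcs * w).sum() / total), float((rows * w).sum() / total))


def classify_column_tuning(profile: ResponseProfile, bw: str,
                           column: WhiskerId | None,
                           trials: dict[str, np.ndarray],
                           config: AnalysisConfig | None = None,
                           rng: np.random.Generator | None = None,
                           cache: _IndicatorCache | None = None) -> str:
    """'CW_tuned', 'nonCW_tuned' or 'septal'.

    Non-CW tuning is assigned conservatively: only when the BW differs from
    the columnar whisker *and* the BW response is significantly greater than
    the CW response by one-sided permutation test.
    """
    if column is None:
        return "septal"
    config = config or profile.config
    if bw == column.label:
        return "CW_tuned"
    if cache is None:
        if rng is None:
            rng = config.rng(103)
        cache = _IndicatorCache(rng, config.n_permutations)
    p = _pair_p(
        np.asarray(trials[bw], float),
        np.asarray(trials[column.label], float),
        cache, "greater",
    )
    return "nonCW_tuned" if p <= config.alpha else "CW_tuned"


_CENTER_OR_EDGE = {"D2", "C2", "D1", "D3", "E2"}  # ≥5 grid-adjacent whiskers


def rank_ordered_curves(profiles: dict[str, ResponseProfile],
                        bw_by_roi: dict[str, str],
                        normalize: str = "to_max") -> pd.DataFrame:
    """Mean descending-sorted tuning curve ± SEM over eligible cells.

    Cells are included only when their BW is the center or a center-edge
    whisker of the 3×3 array (≥5 sampled adjacent whiskers). Negative means
    are retained. ``to_max`` divides each curve by its strongest response;
    ``to_blank`` divides by the cell's blank-trial evoked SD (noise-floor
    units).
    """
    if normalize not in ("to_max", "to_blank"):
        raise ValueError(f"unknown normalize mode {normalize!r}")
    curves = []
    for roi_id, bw in bw_by_roi.items():
        if bw not in _CENTER_OR_EDGE:
            continue
        pr = profiles[roi_id]
        means = np.nan_to_num(pr.mean, nan=0.0)
        curve = np.sort(means)[::-1]
        if normalize == "to_max":
            if curve[0] <= 0:
                continue
            curve = curve / curve[0]
        else:
            if pr.blank_sd <= 0:
                continue
            curve = curve / pr.blank_sd
        curves.append(curve)
    if not curves:
        return pd.DataFrame(columns=["rank", "mean", "sem", "n_cells"])
    arr = np.vstack(curves)
    sem = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0]) if arr.shape[0] > 1 \
        else np.zeros(arr.shape[1])
    return pd.DataFrame({
        "rank": np.arange(1, arr.shape[1] + 1),
        "mean": arr.mean(axis=0),
        "sem": sem,
        "n_cells": arr.shape[0],
    })


@dataclass
class TuningSummary:
    """Per-cell tuning statistics for one session."""

    roi_id: str
    bw: str
    ebw: list[str]
    broadly_tuned: bool
    sharpness: float | None
    cwdi: float | None
    cw_pref: float | None
    com: tuple[float, float] | None
    column: str | None               # column label, or None for septal/excluded
    column_class: str                # CW_tuned | nonCW_tuned | septal
    config: AnalysisConfig = field(default_factory=AnalysisConfig)


def compute_tuning_summaries(table, profiles: dict[str, ResponseProfile],
                             column_by_roi: dict[str, WhiskerId | None],
                             config: AnalysisConfig | None = None,
                             rng: np.random.Generator | None = None,
                             ) -> dict[str, TuningSummary]:
    """Tuning summaries for every responsive ROI in a filtered trial table.

    ``column_by_roi`` maps roi_id to its anatomical column (None = septal);
    ROIs absent from the mapping are treated as excluded and skipped.
    """
    first = next(iter(profiles.values()), None)
    config = config or (first.config if first else AnalysisConfig())
    if rng is None:
        rng = config.rng(104)
    cache = _IndicatorCache(rng, config.n_permutations)
    out: dict[str, TuningSummary] = {}
    for roi_id, pr in profiles.items():
        if not pr.responsive or roi_id not in column_by_roi:
            continue
        trials = table.whisker_evoked(roi_id)
        bw, ebw = find_bw_and_ebw(pr, trials, config, cache=cache)
        column = column_by_roi[roi_id]
        cls = classify_column_tuning(pr, bw, column, trials, config, cache=cache)
        out[roi_id] = TuningSummary(
            roi_id=roi_id,
            bw=bw,
            ebw=ebw,
            broadly_tuned=len(ebw) > 1,
            sharpness=tuning_sharpness(pr, bw),
            cwdi=(cw_dominance_index(pr, column) if column is not None else None),
            cw_pref=(cw_preference(pr, column) if column is not None else None),
            com=tuning_com(pr),
            column=(column.label if column is not None else None),
            column_class=cls,
            config=config,
        )
    return out


def summaries_to_frame(summaries: dict[str, TuningSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries.values():
        rows.append({
            "roi_id": s.roi_id,
            "bw": s.bw,
            "ebw": "|".join(s.ebw),
            "broadly_tuned": s.broadly_tuned,
            "sharpness": s.sharpness,
            "cwdi": s.cwdi,
            "cw_pref": s.cw_pref,
            "com_x": None if s.com is None else s.com[0],
            "com_y": None if s.com is None else s.com[1],
            "column": s.column,
            "column_class": s.column_class,
        })
    return pd.DataFrame(rows)
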