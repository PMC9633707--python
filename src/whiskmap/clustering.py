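"""Spatial clustering of similarly tuned neurons within columns.

Tuning similarity between co-columnar responsive pairs (signal correlation,
ΔCoM, shared BW, response-magnitude similarity) is profiled against
inter-soma distance in 10 µm bins. Two null machineries test for structure:
a within-column spatial shuffle of cell positions, and the
regression-extrapolation excess test, which fits the 30–200 µm distance
profile and asks whether the sub-20 µm bins exceed the extrapolated
gradient (bootstrap of within-bin pair means, BH-corrected).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import AnalysisConfig, RoiRecord
from .responsiveness import ResponseProfile
from .tuning import TuningSummary, _zeroed
from statsmodels.stats.multitest import multipletests

__all__ = [
    "pairwise_similarity",
    "binned_profile",
    "spatial_shuffle_null",
    "cluster_excess_test",
    "cluster_index",
    "cluster_indices",
]

METRICS = ("signal_correlation", "delta_com", "same_bw", "magnitude_similarity")


def _signal_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two zeroed mean-response vectors (NaN if flat)."""
    a = _zeroed(a)
    b = _zeroed(b)
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def pairwise_similarity(profiles: dict[str, ResponseProfile],
                        summaries: dict[str, TuningSummary],
                        rois: dict[str, RoiRecord],
                        scope: str = "co_columnar") -> pd.DataFrame:
    """All tuning-similarity metrics for responsive cell pairs.

    ``co_columnar`` restricts pairs to cells in the same column and imaging
    field (distances across fields are meaningless). ``magnitude_similarity``
    is |R_a − R_b| / |R_a + R_b| on BW response magnitudes, i.e. 0 for equal
    magnitudes.
    """
    if scope != "co_columnar":
        raise ValueError(f"unknown scope {scope!r}")
    cells = [
        roi_id for roi_id, s in summaries.items()
        if s.column is not None and roi_id in rois
    ]
    rows = []
    by_group: dict[tuple[str, str], list[str]] = {}
    for roi_id in cells:
        key = (rois[roi_id].field_id, summaries[roi_id].column)
        by_group.setdefault(key, []).append(roi_id)
    for (field_id, column), group in by_group.items():
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                a, b = group[i], group[j]
                ra, rb = rois[a], rois[b]
                dist = float(np.hypot(ra.x - rb.x, ra.y - rb.y))
                sa, sb = summaries[a], summaries[b]
                bwa = profiles[a].mean[profiles[a].whisker_index(sa.bw)]
                bwb = profiles[b].mean[profiles[b].whisker_index(sb.bw)]
                denom = abs(bwa + bwb)
                if sa.com is not None and sb.com is not None:
                    dcom = float(np.hypot(sa.com[0] - sb.com[0],
                                          sa.com[1] - sb.com[1]))
                else:
                    dcom = np.nan
                rows.append({
                    "roi_a": a,
                    "roi_b": b,
                    "field_id": field_id,
                    "column": column,
                    "distance_um": dist,
                    "signal_correlation": _signal_correlation(
                        profiles[a].mean, profiles[b].mean),
                    "delta_com": dcom,
                    "same_bw": float(sa.bw == sb.bw),
                    "magnitude_similarity": (abs(bwa - bwb) / denom
                                             if denom > 0 else np.nan),
                })
    return pd.DataFrame(
        rows, columns=["roi_a", "roi_b", "field_id", "column", "distance_um",
                       *METRICS],
    )


def _bin_index(dist: np.ndarray, width: float) -> np.ndarray:
    return np.floor(np.asarray(dist, float) / width).astype(int)


def binned_profile(pairs: pd.DataFrame, metric: str,
                   config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Per-distance-bin mean ± SEM of a similarity metric.

    Bins are half-open [k·w, (k+1)·w) µm; bins with no pairs are omitted.
    """
    config = config or AnalysisConfig()
    if len(pairs) == 0:
        raise ValueError("need at least one pair")
    w = config.bin_width_um
    d = pairs["distance_um"].to_numpy(float)
    v = pairs[metric].to_numpy(float)
    keep = np.isfinite(v)
    d, v = d[keep], v[keep]
    idx = _bin_index(d, w)
    rows = []
    for k in np.unique(idx):
        vals = v[idx == k]
        rows.append({
            "bin_lo": k * w,
            "bin_hi": (k + 1) * w,
            "mean": vals.mean(),
            "sem": (vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0,
            "count": vals.size,
        })
    return pd.DataFrame(rows)


def spatial_shuffle_null(pairs: pd.DataFrame, rois: dict[str, RoiRecord],
                         columns_by_roi: dict[str, str], metric: str,
                         n_iter: int = 10_000,
                         rng: np.random.Generator | None = None,
                         config: AnalysisConfig | None = None,
                         seed: int | None = None) -> pd.DataFrame:
    """Within-column position-shuffle null for a binned similarity profile.

    Each iteration permutes cell positions within every (field, column)
    group — preserving the multiset of positions and of tuning vectors — and
    re-bins the fixed pair metrics against the shuffled distances. Returns
    the per-bin null mean and 95% percentile CI.
    """
    config = config or AnalysisConfig()
    if rng is None:
        rng = np.random.default_rng(seed)
    w = config.bin_width_um
    cell_ids = sorted({*pairs["roi_a"], *pairs["roi_b"]})
    pos = np.array([[rois[c].x, rois[c].y] for c in cell_ids])
    index = {c: i for i, c in enumerate(cell_ids)}
    ia = pairs["roi_a"].map(index).to_numpy()
    ib = pairs["roi_b"].map(index).to_numpy()
    v = pairs[metric].to_numpy(float)
    keep = np.isfinite(v)
    ia, ib, v = ia[keep], ib[keep], v[keep]
    groups = {}
    for c in cell_ids:
        key = (rois[c].field_id, columns_by_roi[c])
        groups.setdefault(key, []).append(index[c])
    group_idx = [np.asarray(g) for g in groups.values()]
    max_bin = int(np.floor(
        max(np.hypot(*(pos[i] - pos[j])) for i, j in zip(ia, ib)) / w
    )) + 2
    sums = np.zeros((n_iter, max_bin))
    counts = np.zeros((n_iter, max_bin))
    perm = np.arange(len(cell_ids))
    for it in range(n_iter):
        for g in group_idx:
            perm[g] = g[rng.permutation(g.size)]
        p = pos[perm]
        d = np.hypot(p[ia, 0] - p[ib, 0], p[ia, 1] - p[ib, 1])
        idx = np.clip(_bin_index(d, w), 0, max_bin - 1)
        sums[it] = np.bincount(idx, weights=v, minlength=max_bin)
        counts[it] = np.bincount(idx, minlength=max_bin)
    with np.errstate(invalid="ignore"):
        means = sums / counts
    rows = []
    for k in range(max_bin):
        col = means[:, k]
        col = col[np.isfinite(col)]
        if col.size == 0:
            continue
        rows.append({
            "bin_lo": k * w,
            "bin_hi": (k + 1) * w,
            "null_mean": col.mean(),
            "ci_lo": np.percentile(col, 2.5),
            "ci_hi": np.percentile(col, 97.5),
            "n_iter_occupied": col.size,
        })
    return pd.DataFrame(rows)


def cluster_excess_test(pairs: pd.DataFrame, metric: str,
                        config: AnalysisConfig | None = None,
                        rng: np.random.Generator | None = None,
                        n_boot: int | None = None,
                        alternative: str = "greater",
                        fit_on: str = "pairs",
                        seed: int | None = None) -> pd.DataFrame:
    """Regression-extrapolation test for sub-20 µm tuning-cluster excess.

    OLS is fit to pair-level (distance, metric) points in the 30–200 µm
    range (``fit_on='bins'`` fits bin means instead) and extrapolated to the
    centers of the bins below the cluster window. Each tested bin's p-value
    is a one-sided bootstrap of the within-bin pair mean against the
    extrapolated expectation; flags are BH-corrected across tested bins.
    For ΔCoM-like metrics where clustering lowers the value, pass
    ``alternative='less'``.
    """
    config = config or AnalysisConfig()
    if rng is None:
        rng = np.random.default_rng(seed)
    if n_boot is None:
        n_boot = config.n_bootstrap
    w = config.bin_width_um
    lo, hi = config.cluster_fit_range_um
    d = pairs["distance_um"].to_numpy(float)
    v = pairs[metric].to_numpy(float)
    keep = np.isfinite(v)
    d, v = d[keep], v[keep]
    fit_mask = (d >= lo) & (d < hi)
    if fit_on == "pairs":
        if np.unique(_bin_index(d[fit_mask], w)).size < 2:
            raise ValueError("need >=2 occupied bins in the fit range")
        res = stats.linregress(d[fit_mask], v[fit_mask])
        slope, intercept = res.slope, res.intercept
    elif fit_on == "bins":
        sub = pairs[pairs[metric].notna()
                    & (pairs["distance_um"] >= lo)
                    & (pairs["distance_um"] < hi)]
        prof = binned_profile(sub, metric, config)
        if len(prof) < 2:
            raise ValueError("need >=2 occupied bins in the fit range")
        centers = (prof["bin_lo"] + prof["bin_hi"]) / 2
        res = stats.linregress(centers, prof["mean"])
        slope, intercept = res.slope, res.intercept
    else:
        raise ValueError(f"unknown fit_on {fit_on!r}")
    n_test = int(np.ceil(config.cluster_window_um / w))
    rows = []
    for k in range(n_test):
        center = (k + 0.5) * w
        expected = slope * center + intercept
        in_bin = v[(d >= k * w) & (d < (k + 1) * w)]
        if in_bin.size == 0:
            rows.append({"bin_lo": k * w, "bin_hi": (k + 1) * w,
                         "expected": expected, "observed": np.nan,
                         "count": 0, "p": np.nan})
            continue
        draws = rng.integers(0, in_bin.size, size=(n_boot, in_bin.size))
        boot_means = in_bin[draws].mean(axis=1)
        if alternative == "greater":
            k_extreme = int((boot_means <= expected).sum())
        else:
            k_extreme = int((boot_means >= expected).sum())
        rows.append({
            "bin_lo": k * w,
            "bin_hi": (k + 1) * w,
            "expected": expected,
            "observed": in_bin.mean(),
            "count": in_bin.size,
            "p": (k_extreme + 1) / (n_boot + 1),
        })
    out = pd.DataFrame(rows)
    tested = out["p"].notna().to_numpy()
    flags = np.zeros(len(out), dtype=bool)
    if tested.any():
        flags[tested] = multipletests(
            out.loc[tested, "p"], alpha=config.fdr_q, method="fdr_bh"
        )[0]
    out["flag"] = flags
    out["slope"] = slope
    out["intercept"] = intercept
    return out


def cluster_index(roi_id: str, pairs: pd.DataFrame,
                  window_um: float = 20.0) -> float:
    """Mean signal correlation with responsive neighbors < 20 µm (NaN if none)."""
    mask = ((pairs["roi_a"] == roi_id) | (pairs["roi_b"] == roi_id)) & \
        (pairs["distance_um"] < window_um)
    vals = pairs.loc[mask, "signal_correlation"].dropna()
    if len(vals) == 0:
        return np.nan
    return float(vals.mean())


def cluster_indices(pairs: pd.DataFrame, roi_ids,
                    window_um: float = 20.0) -> dict[str, float]:
    """Vectorized :func:`cluster_index` for many cells."""
    near = pairs[(pairs["distance_um"] < window_um)
                 & pairs["signal_correlation"].notna()]
    sums: dict[str, float] = {r: 0.0 for r in roi_ids}
    counts: dict[str, int] = {r: 0 for r in roi_ids}
    for a, b, sc in zip(near["roi_a"], near["roi_b"],
                        near["signal_correlation"]):
        for r in (a, b):
            if r in sums:
                sums[r] += sc
                counts[r] += 1
    return {
        r: (sums[r] / counts[r] if counts[r] else np.nan) for r in roi_ids
    }
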