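"""High-level orchestration joining the per-module stages.

These helpers run the standard analysis path on in-memory objects: per
session responsiveness → per-cell BW → cross-session stability records →
initial-session covariates for the change-prediction model. The CLI and the
reproduction script are thin wrappers around them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import AnalysisConfig, BarrelMap, RoiRecord, TrialTable
from .responsiveness import ResponseProfile, compute_response_profiles
from .stability import classify_stability
from .tuning import _IndicatorCache, find_bw_and_ebw

__all__ = [
    "session_bw",
    "stability_records",
    "initial_covariates",
]


def session_bw(table: TrialTable, profiles: dict[str, ResponseProfile],
               config: AnalysisConfig,
               cache: _IndicatorCache | None = None) -> dict[str, str]:
    """Nominal best whisker for every responsive ROI in one session."""
    if cache is None:
        cache = _IndicatorCache(config.rng(110), config.n_permutations)
    out = {}
    for roi_id, pr in profiles.items():
        if pr.responsive:
            bw, _ = find_bw_and_ebw(pr, table.whisker_evoked(roi_id),
                                    config, cache=cache)
            out[roi_id] = bw
    return out


def stability_records(tables: list[TrialTable],
                      config: AnalysisConfig | None = None,
                      n_iter: int | None = None,
                      pairs: list[tuple[int, int]] | None = None,
                      ) -> pd.DataFrame:
    """Responsiveness-transition and tuning-change records for session pairs.

    ``tables`` are filtered single-session trial tables sharing ROI ids
    (the cross-session key). By default every ordered pair (i < j) is
    classified, giving the full Δ1/Δ2/Δ3 record set for 4 sessions.
    """
    config = config or tables[0].config
    rng = config.rng(111)
    cache = _IndicatorCache(rng, config.n_permutations)
    sessions = []
    for table in tables:
        profiles = compute_response_profiles(table, config, rng)
        bw = session_bw(table, profiles, config, cache)
        trials = {roi: table.whisker_evoked(roi) for roi in table.roi_ids}
        sessions.append({"profiles": profiles, "bw": bw, "trials": trials})
    if pairs is None:
        n = len(tables)
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    roi_ids = tables[0].roi_ids
    rows = []
    for i, j in pairs:
        si, sj = sessions[i], sessions[j]
        for roi in roi_ids:
            resp_i = si["profiles"][roi].responsive
            resp_j = sj["profiles"][roi].responsive
            sig_j = [
                sj["profiles"][roi].whiskers[k]
                for k in np.flatnonzero(sj["profiles"][roi].significant_positive)
            ]
            rec = classify_stability(
                roi, i, j, resp_i, resp_j,
                si["trials"][roi] if resp_i and resp_j else None,
                sj["trials"][roi] if resp_i and resp_j else None,
                prior_bw=si["bw"].get(roi),
                significant_j=sig_j,
                config=config, rng=rng, cache=cache, n_iter=n_iter,
            )
            rows.append({
                "cross_session_key": roi,
                "session_i": i,
                "session_j": j,
                "interval": rec.interval,
                "transition": rec.transition,
                "tuning_class": rec.tuning_class,
                "new_bw": rec.new_bw,
                "delta_com_magnitude": rec.delta_com_magnitude,
                "prior_bw": si["bw"].get(roi),
            })
    return pd.DataFrame(rows)


def initial_covariates(table: TrialTable, barrel_map: BarrelMap,
                       rois: dict[str, RoiRecord],
                       config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Session-1 covariates for the change-prediction model.

    Per responsive cell: map location (distance to its BW column center, in
    column radii), BW response magnitude, tuning sharpness, cluster index,
    and CW/non-CW class.
    """
    from .clustering import cluster_indices, pairwise_similarity
    from .map_geometry import assign_columns, normalize_position
    from .tuning import compute_tuning_summaries

    config = config or table.config
    profiles = compute_response_profiles(table, config)
    assignment = assign_columns(
        [rois[r] for r in table.roi_ids if r in rois], barrel_map, config)
    column_by_roi = {
        roi_id: (col if not isinstance(col, str) else None)
        for roi_id, col in assignment.items() if col != "excluded"
    }
    summaries = compute_tuning_summaries(table, profiles, column_by_roi,
                                         config)
    pair_df = pairwise_similarity(profiles, summaries, rois)
    cidx = cluster_indices(pair_df, list(summaries))
    rows = []
    for roi_id, s in summaries.items():
        np_pos = normalize_position(rois[roi_id],
                                    barrel_map.column(s.bw).whisker,
                                    barrel_map)
        pr = profiles[roi_id]
        rows.append({
            "cross_session_key": rois[roi_id].cross_session_key or roi_id,
            "roi_id": roi_id,
            "bw": s.bw,
            "location": np_pos.radius,
            "magnitude": pr.mean[pr.whisker_index(s.bw)],
            "sharpness": s.sharpness,
            "cluster_index": cidx.get(roi_id, np.nan),
            "column_class": s.column_class,
        })
    return pd.DataFrame(rows)
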