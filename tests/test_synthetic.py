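"""Generator: map geometry, ground-truth tuning, trial statistics, drift."""

import numpy as np
import pytest

from whiskmap.data_model import ALL_WHISKERS
from whiskmap.map_geometry import column_radius
from whiskmap.synthetic import (
    SimulationConfig,
    apply_drift,
    make_barrel_map,
    sample_cells,
    simulate_experiment,
    simulate_session,
)

_LABELS = [w.label for w in ALL_WHISKERS]


class TestMakeBarrelMap:
    def test_nine_columns_d2_at_origin(self):
        m = make_barrel_map()
        assert len(m.columns) == 9
        assert m.column("D2").centroid == (0.0, 0.0)

    def test_apothem_distance(self):
        cfg = SimulationConfig(apothem_um=55.0)
        col = make_barrel_map(cfg).column("D2")
        # ray along an apothem direction (+x for this hexagon orientation)
        assert column_radius(col, np.array([1.0, 0.0])) == \
            pytest.approx(55.0, abs=1e-9)

    def test_column_areas_equal(self):
        m = make_barrel_map()
        areas = [c.boundary.area for c in m.columns]
        assert np.ptp(areas) < 1e-9 * areas[0]

    def test_row_arc_layout(self):
        m = make_barrel_map()
        c1, e3 = m.column("C1").centroid, m.column("E3").centroid
        assert c1[0] < e3[0]  # arcs increase along +x
        assert c1[1] > e3[1]  # row C above row E


class TestSampleCells:
    def test_cw_fraction_within_binomial_ci(self):
        cfg = SimulationConfig(cells_per_column=250, cw_tuned_fraction=0.52,
                               gradient_strength=0.0, cluster_strength=0.0,
                               seed=3)
        rng = cfg.rng()
        m = make_barrel_map(cfg)
        _, truth = sample_cells(cfg, m, rng)
        columnar = (truth.column != "septal") & truth.base_responsive
        frac = truth.initial_cw_tuned[columnar].mean()
        n = columnar.sum()
        assert n > 400
        half = 1.96 * np.sqrt(0.52 * 0.48 / n)
        assert abs(frac - 0.52) < half + 0.01

    def test_cw_fraction_one_means_all_columnar_cw(self):
        cfg = SimulationConfig(cells_per_column=40, cw_tuned_fraction=1.0,
                               cluster_strength=0.0, seed=4)
        rng = cfg.rng()
        m = make_barrel_map(cfg)
        _, truth = sample_cells(cfg, m, rng)
        columnar = (truth.column != "septal") & truth.base_responsive
        assert truth.initial_cw_tuned[columnar].all()

    def test_no_structure_means_position_independent_peaks(self):
        cfg = SimulationConfig(cells_per_column=60, gradient_strength=0.0,
                               cluster_strength=0.0, cw_tuned_fraction=0.0,
                               responsive_fraction=1.0, seed=5)
        rng = cfg.rng()
        m = make_barrel_map(cfg)
        rois, truth = sample_cells(cfg, m, rng)
        pos = np.array([[r.x, r.y] for r in rois])
        # same-peak probability for close pairs vs distant pairs
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(pos))
        same = truth.peak[:, None] == truth.peak[None, :]
        iu = np.triu_indices(len(rois), 1)
        close = d[iu] < 20
        p_close = same[iu][close].mean()
        p_far = same[iu][~close].mean()
        assert abs(p_close - p_far) < 0.08

    def test_positions_within_inclusion_region(self):
        from whiskmap.map_geometry import assign_columns

        cfg = SimulationConfig(cells_per_column=20, seed=6)
        m = make_barrel_map(cfg)
        rois, _ = sample_cells(cfg, m, cfg.rng())
        assignment = assign_columns(rois, m)
        assert all(a != "excluded" for a in assignment.values())


class TestSimulateSession:
    def test_zero_noise_recovers_true_surface_exactly(self):
        cfg = SimulationConfig(cells_per_column=5, blank_noise_sd=0.0,
                               trial_gain_sd=0.0, lick_prob=0.0, seed=7,
                               suppressed_fraction=0.0)
        m = make_barrel_map(cfg)
        rois, truth = sample_cells(cfg, m, cfg.rng())
        table = simulate_session(rois, truth, cfg, 0, np.random.default_rng(1))
        surface = truth.surface
        for ci, roi in enumerate(rois):
            ev = table.whisker_evoked(roi.roi_id)
            for wi, label in enumerate(_LABELS):
                assert np.allclose(ev[label], surface[ci, wi])

    def test_nonresponsive_cell_whisker_equals_blank_distribution(self):
        cfg = SimulationConfig(cells_per_column=5, responsive_fraction=0.0,
                               waver_gain=0.0, seed=8)
        m = make_barrel_map(cfg)
        rois, truth = sample_cells(cfg, m, cfg.rng())
        table = simulate_session(rois, truth, cfg, 0, np.random.default_rng(2))
        roi = rois[0].roi_id
        whisk = np.concatenate(list(table.whisker_evoked(roi).values()))
        blank = table.blank_evoked(roi)
        from scipy.stats import ks_2samp

        assert ks_2samp(whisk, blank).pvalue > 0.01

    def test_blank_mean_within_clt_bound(self):
        cfg = SimulationConfig(cells_per_column=5, blank_trials=50, seed=9)
        m = make_barrel_map(cfg)
        rois, truth = sample_cells(cfg, m, cfg.rng())
        table = simulate_session(rois, truth, cfg, 0, np.random.default_rng(3))
        blank = table.blank_evoked(rois[0].roi_id)
        assert blank.size == 50
        assert abs(blank.mean()) < 3 * cfg.blank_noise_sd / np.sqrt(50)


class TestApplyDrift:
    def _truth(self, seed=10, **kw):
        kw.setdefault("cells_per_column", 40)
        cfg = SimulationConfig(responsive_fraction=1.0, seed=seed, **kw)
        m = make_barrel_map(cfg)
        _, truth = sample_cells(cfg, m, cfg.rng())
        return cfg, truth

    def test_zero_drift_is_identity(self):
        cfg, truth = self._truth(drift_noncw=0.0, drift_cw=0.0,
                                 com_jitter_fraction=0.0)
        new, log = apply_drift(truth, cfg, 1, np.random.default_rng(0))
        np.testing.assert_array_equal(new.peak, truth.peak)
        np.testing.assert_allclose(new.base_surface, truth.base_surface)
        assert (log["kind"] == "none").all()

    def test_full_noncw_drift_no_cw_drift(self):
        cfg, truth = self._truth(drift_noncw=1.0, drift_cw=0.0,
                                 com_jitter_fraction=0.0)
        new, log = apply_drift(truth, cfg, 1, np.random.default_rng(0))
        cw = truth.initial_cw_tuned
        resp = truth.base_responsive
        shifted = log.set_index("roi")["kind"] == "BW_shift"
        for i in np.flatnonzero(resp):
            if cw[i]:
                assert not shifted.get(i, False)
                assert new.peak[i] == truth.peak[i]
            else:
                assert shifted.get(i, False)

    def test_drift_fractions_within_binomial_ci(self):
        cfg, truth = self._truth(seed=12, drift_noncw=0.3, drift_cw=0.05,
                                 com_jitter_fraction=0.0,
                                 cells_per_column=120)
        new, log = apply_drift(truth, cfg, 1, np.random.default_rng(1))
        shifted = set(log.loc[log["kind"] == "BW_shift", "roi"])
        for cls_mask, p in ((truth.initial_cw_tuned, 0.05),
                            (~truth.initial_cw_tuned, 0.3)):
            idx = np.flatnonzero(truth.base_responsive & cls_mask)
            frac = np.mean([i in shifted for i in idx])
            half = 1.96 * np.sqrt(p * (1 - p) / idx.size)
            assert abs(frac - p) < half + 0.01

    def test_all_shifts_grid_adjacent(self):
        cfg, truth = self._truth(seed=13, drift_noncw=1.0, drift_cw=1.0,
                                 com_jitter_fraction=0.0)
        new, _ = apply_drift(truth, cfg, 1, np.random.default_rng(2))
        for old, newp in zip(truth.peak, new.peak):
            if old != newp:
                assert ALL_WHISKERS[newp] in ALL_WHISKERS[old].neighbors()

    def test_com_jitter_preserves_bw(self):
        cfg, truth = self._truth(seed=14, drift_noncw=0.0, drift_cw=0.0,
                                 com_jitter_fraction=1.0)
        new, log = apply_drift(truth, cfg, 1, np.random.default_rng(3))
        assert (log.loc[log["kind"] != "none", "kind"] == "CoM_jitter").all()
        np.testing.assert_array_equal(
            new.base_surface.argmax(axis=1)[truth.base_responsive],
            truth.peak[truth.base_responsive],
        )


class TestDeterminism:
    def test_identical_config_and_seed_bit_identical(self):
        cfg = SimulationConfig(cells_per_column=8, n_sessions=2, seed=42)
        a = simulate_experiment(cfg)
        b = simulate_experiment(cfg)
        for ta, tb in zip(a.sessions, b.sessions):
            np.testing.assert_array_equal(ta.dff.to_numpy(), tb.dff.to_numpy())
            assert ta.trials.equals(tb.trials)
        np.testing.assert_array_equal(a.truths[1].base_surface,
                                      b.truths[1].base_surface)

    def test_generated_tables_pass_validation(self, small_experiment):
        for table in small_experiment.sessions:
            table.validate()  # raises on any invariant violation
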