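"""Sampling-window contract: efficiency floor, geometry, validation."""

import numpy as np
import pytest

from popkdesign import (
    Design,
    DesignConstraints,
    DesignEvaluator,
    Group,
    SearchConfig,
    WindowSet,
    Window,
    find_windows,
    optimize,
    validate_windows,
)


@pytest.fixture(scope="module")
def toy_opt(request):
    """Optimised 3-point design for a small single-model set (module-cached)."""
    from popkdesign import DOST, build_competing_set, build_population_model

    pm = build_population_model(
        DOST, theta={"k": 1.0, "v_f": 40.0, "tlag": 0.0},
        bsv_cv={"k": 20.0, "v_f": 30.0}, sigma_prop=0.2, sigma_add=0.02,
        fixed_theta=("tlag",), label="toy",
    )
    cset = build_competing_set([(pm, {})], central_weight=1.0)
    template = Design(groups=[Group(30, np.array([0.5, 2.0, 6.0]))],
                      constraints=DesignConstraints(horizon=12.0))
    res = optimize(cset, template,
                   SearchConfig(grid_resolution=0.1, coarse_factor=2,
                                n_multistart=4, seed=1))
    return cset, res


class TestFindWindows:
    def test_floor_one_collapses_to_points(self, toy_opt):
        cset, res = toy_opt
        ws = find_windows(res, cset, floor=1.0, n_mc=400, seed=2,
                          grid_resolution=0.1)
        assert ws.notice != ""
        for wlist, times in zip(ws.windows, ws.times):
            for w, t in zip(wlist, times):
                assert w.width <= 0.1 + 1e-9

    def test_windows_contain_optima_and_respect_geometry(self, toy_opt):
        cset, res = toy_opt
        ws = find_windows(res, cset, floor=0.8, n_mc=600, seed=2,
                          grid_resolution=0.1)
        cons = res.design.constraints
        for wlist, times in zip(ws.windows, ws.times):
            for w, t in zip(wlist, times):
                assert w.lo - 1e-9 <= t <= w.hi + 1e-9
                assert w.lo >= cons.t_min - 1e-9 and w.hi <= cons.horizon + 1e-9
            for a, b in zip(wlist[:-1], wlist[1:]):
                assert b.lo >= a.hi - 1e-9          # order-preserving
                assert b.hi >= a.hi + cons.min_spacing - 1e-9

    def test_monte_carlo_contract_holds_on_fresh_draws(self, toy_opt):
        """Designs drawn inside the returned windows keep >=95% of draws at
        or above the efficiency floor."""
        cset, res = toy_opt
        ws = find_windows(res, cset, floor=0.8, n_mc=800, seed=2,
                          grid_resolution=0.1)
        ev = DesignEvaluator(cset, res.design)
        obj_opt = ev.objective([g.times for g in res.design.groups])
        rng = np.random.default_rng(77)
        lo = np.array([w.lo for w in ws.windows[0]])
        hi = np.array([w.hi for w in ws.windows[0]])
        from popkdesign.windows import _sample_in_windows
        samp = _sample_in_windows(rng, lo, hi, res.design.constraints.min_spacing,
                                  1000)
        eff = np.exp(ev.objective_batch([samp]) - obj_opt)
        assert np.mean(eff >= 0.8) >= 0.95

    def test_bad_floor_rejected(self, toy_opt):
        cset, res = toy_opt
        with pytest.raises(ValueError):
            find_windows(res, cset, floor=0.0)


class TestValidateWindows:
    def test_point_windows_have_unit_efficiency(self, toy_opt):
        cset, res = toy_opt
        t = res.design.groups[0].times
        ws = WindowSet(windows=[[Window(x, x) for x in t]], times=[list(t)])
        out = validate_windows(ws, cset, res.design, n_mc=200, seed=0)
        assert out["min"] == pytest.approx(1.0, abs=1e-9)

    def test_overwide_windows_fail_loudly(self, toy_opt):
        cset, res = toy_opt
        ws = find_windows(res, cset, floor=0.8, n_mc=600, seed=2,
                          grid_resolution=0.1)
        t = res.design.groups[0].times
        cons = res.design.constraints
        wide = []
        for j, w in enumerate(ws.windows[0]):
            lo = max(cons.t_min, t[j] - 3 * (t[j] - w.lo) - 0.5)
            hi = min(cons.horizon, t[j] + 3 * (w.hi - t[j]) + 0.5)
            wide.append(Window(lo, hi))
        # keep them non-overlapping for validity
        for j in range(len(wide) - 1):
            if wide[j].hi > wide[j + 1].lo:
                mid = 0.5 * (t[j] + t[j + 1])
                wide[j] = Window(wide[j].lo, mid)
                wide[j + 1] = Window(mid, wide[j + 1].hi)
        ws_wide = WindowSet(windows=[wide], times=[list(t)])
        out = validate_windows(ws_wide, cset, res.design, n_mc=800, seed=3)
        assert out["min"] < 0.8

    def test_validation_stable_across_seeds(self, toy_opt):
        cset, res = toy_opt
        ws = find_windows(res, cset, floor=0.8, n_mc=600, seed=2,
                          grid_resolution=0.1)
        a = validate_windows(ws, cset, res.design, n_mc=5000, seed=1,
                             percentile=5.0)
        b = validate_windows(ws, cset, res.design, n_mc=5000, seed=2,
                             percentile=5.0)
        assert abs(a["percentile"] - b["percentile"]) < 0.01

    def test_overlapping_windows_rejected(self, toy_opt):
        cset, res = toy_opt
        t = res.design.groups[0].times
        bad = [Window(t[0] - 0.2, t[0] + 1.0), Window(t[1] - 1.0, t[1] + 0.2),
               Window(t[2] - 0.1, t[2] + 0.1)]
        with pytest.raises(ValueError):
            WindowSet(windows=[bad], times=[list(t)])
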