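"""Sampling windows around the optimal times with a guaranteed efficiency
floor.

A window set assigns each optimal time an interval [lo, hi]; field teams may
draw the sample anywhere inside, and the design keeps at least the stated
fraction (default 0.80) of the optimal design's overall D-efficiency.  The
procedure here:

1. For each time in turn (others held at their optima), bisect the largest
   half-width whose in-window Monte-Carlo draws all keep the efficiency
   criterion above the floor.  These caps are proportional to the local
   information sensitivity of each sampling time.
2. Bisect a single global shrink factor on those caps so that *joint*
   sampling in all windows simultaneously meets the floor.  Common random
   numbers are used throughout, so the procedure is deterministic given the
   seed and the bisection boundary is smooth.

The default guarantee is worst-case over the sampled joint designs (strict
minimum), so the promise holds for every draw a field team might take; a
percentile criterion (e.g. the 5th percentile) is available as a softer
contract.

Windows expand asymmetrically when a symmetric expansion would cross the
start of the horizon or a neighbouring window: the blocked width is
redistributed to the feasible side.  Upper edges of consecutive windows stay
at least the minimum sample spacing apart so the sequential in-window
sampler is always feasible.  The efficiency of a sampled design against the
optimum is the weighted geometric mean over the competing models,
exp(objective difference) of the compound criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fim import Design, DesignEvaluator
from .population import CompetingModelSet
from .search import OptimalDesignResult


@dataclass(frozen=True)
class Window:
    lo: float
    hi: float

    @property
    def width(self) -> float:
        return self.hi - self.lo


@dataclass
class WindowSet:
    """Per-group, per-time sampling windows plus the validated efficiency."""

    windows: list                 # list (per group) of lists of Window
    times: list                   # matching optimal times
    efficiency_floor: float = 0.80
    validation: float = np.nan    # achieved criterion efficiency (fresh draws)
    notice: str = ""

    def __post_init__(self):
        for ws, ts in zip(self.windows, self.times):
            for w, t in zip(ws, ts):
                if not (w.lo <= t <= w.hi):
                    raise ValueError("each window must contain its optimal time")
            for a, b in zip(ws[:-1], ws[1:]):
                if b.lo < a.hi - 1e-9:
                    raise ValueError("windows within a group must not overlap")

    def as_records(self) -> list:
        out = []
        for ig, (ws, ts) in enumerate(zip(self.windows, self.times)):
            for w, t in zip(ws, ts):
                out.append({"group": ig, "time": t, "lo": w.lo, "hi": w.hi})
        return out


def _map_to_windows(u, lo, hi, spacing):
    """Map uniform(0,1) draws to sequential truncated-uniform joint samples
    respecting the spacing (common-random-number form)."""
    n_mc, n = u.shape
    out = np.empty((n_mc, n))
    prev = np.full(n_mc, -np.inf)
    for j in range(n):
        low = np.maximum(lo[j], prev + spacing)
        width = np.maximum(hi[j] - low, 0.0)
        out[:, j] = low + u[:, j] * width
        prev = out[:, j]
    return out


def _sample_in_windows(rng, lo, hi, spacing, n_mc):
    """Sequential truncated-uniform joint draws respecting the spacing."""
    return _map_to_windows(rng.random((n_mc, len(lo))), lo, hi, spacing)


def _layout(times, widths, constraints):
    """Edges from desired half-widths: clip at the horizon ends with
    redistribution, split overlap between neighbours at the midpoint, and
    keep consecutive upper edges >= spacing apart."""
    times = np.asarray(times, float)
    widths = np.asarray(widths, float)
    lo = times - widths
    hi = times + widths
    # redistribute at the lower/upper horizon bounds
    for j in range(len(times)):
        if lo[j] < constraints.t_min:
            hi[j] += constraints.t_min - lo[j]
            lo[j] = constraints.t_min
        if hi[j] > constraints.horizon:
            lo[j] -= hi[j] - constraints.horizon
            hi[j] = constraints.horizon
    # resolve neighbour overlap at the midpoint of the conflict
    for j in range(len(times) - 1):
        if hi[j] > lo[j + 1]:
            b = 0.5 * (hi[j] + lo[j + 1])
            b = min(max(b, times[j]), times[j + 1])
            hi[j], lo[j + 1] = b, b
    # sequential sampler feasibility: upper edges spaced by >= min_spacing
    for j in range(len(times) - 2, -1, -1):
        hi[j] = min(hi[j], hi[j + 1] - constraints.min_spacing)
    lo = np.minimum(lo, times)
    hi = np.maximum(hi, times)
    return lo, hi


def _joint_efficiency(evaluator, lo_list, hi_list, constraints, rng, n_mc, obj_opt):
    samples = [
        _sample_in_windows(rng, lo, hi, constraints.min_spacing, n_mc)
        for lo, hi in zip(lo_list, hi_list)
    ]
    obj = evaluator.objective_batch(samples)
    return np.exp(obj - obj_opt)


def find_windows(opt: OptimalDesignResult, cset: CompetingModelSet,
                 floor: float = 0.80, n_mc: int = 5000, seed: int = 0,
                 percentile: float = 0.0, block_diagonal: bool = False,
                 grid_resolution: float = 1.0 / 60.0) -> WindowSet:
    """Compute sampling windows guaranteeing ``floor`` overall efficiency."""
    if not 0.0 < floor <= 1.0:
        raise ValueError("efficiency floor must lie in (0, 1]")
    design = opt.design
    cons = design.constraints
    evaluator = DesignEvaluator(cset, design, block_diagonal=block_diagonal)
    base_times = [g.times for g in design.groups]
    obj_opt = evaluator.objective(base_times)
    rng = np.random.default_rng(seed)
    q = percentile

    tol = grid_resolution / 2.0
    # common random numbers: one fixed uniform draw per (design, time)
    u_draws = [rng.random((n_mc, len(t_g))) for t_g in base_times]

    def edges_at(widths):
        lo_list, hi_list = [], []
        for t_g, w_g in zip(base_times, widths):
            lo, hi = _layout(t_g, w_g, cons)
            lo_list.append(lo)
            hi_list.append(hi)
        return lo_list, hi_list

    def joint_ok(widths):
        lo_list, hi_list = edges_at(widths)
        samples = [
            _map_to_windows(u, lo, hi, cons.min_spacing)
            for u, lo, hi in zip(u_draws, lo_list, hi_list)
        ]
        eff = np.exp(evaluator.objective_batch(samples) - obj_opt)
        return float(np.percentile(eff, q)) >= floor, lo_list, hi_list

    # stage 1: per-time caps with every other time held at its optimum
    caps = [np.zeros(len(t_g)) for t_g in base_times]
    for ig, t_g in enumerate(base_times):
        for j in range(len(t_g)):
            lo_cap = cons.t_min if j == 0 else t_g[j - 1]
            hi_cap = cons.horizon if j == len(t_g) - 1 else t_g[j + 1]
            w_max = max(t_g[j] - lo_cap, hi_cap - t_g[j])
            lo_w, hi_w = 0.0, w_max
            while hi_w - lo_w > tol:
                w = 0.5 * (lo_w + hi_w)
                trial = [np.zeros(len(t)) for t in base_times]
                trial[ig][j] = w
                ok, _, _ = joint_ok(trial)
                if ok:
                    lo_w = w
                else:
                    hi_w = w
            caps[ig][j] = lo_w

    # stage 2: global shrink factor for the joint contract
    lo_s, hi_s = 0.0, 1.0
    for _ in range(14):
        s = 0.5 * (lo_s + hi_s)
        ok, _, _ = joint_ok([s * c for c in caps])
        if ok:
            lo_s = s
        else:
            hi_s = s
    lo_list, hi_list = edges_at([lo_s * c for c in caps])

    eff = _joint_efficiency(evaluator, lo_list, hi_list, cons,
                            np.random.default_rng(seed + 2), n_mc, obj_opt)
    validation = float(np.percentile(eff, q))
    notice = ""
    if all(np.all(hi - lo <= grid_resolution + 1e-9)
           for lo, hi in zip(lo_list, hi_list)):
        notice = "windows degenerate to the optimal times at this floor"
    windows = [
        [Window(float(l), float(h)) for l, h in zip(lo, hi)]
        for lo, hi in zip(lo_list, hi_list)
    ]
    return WindowSet(windows=windows, times=[list(map(float, t)) for t in base_times],
                     efficiency_floor=floor, validation=validation, notice=notice)


def validate_windows(ws: WindowSet, cset: CompetingModelSet, design: Design,
                     n_mc: int = 5000, seed: int = 0, percentile: float = 0.0,
                     block_diagonal: bool = False) -> dict:
    """Empirical minimum and percentile efficiency over in-window designs."""
    for group_ws in ws.windows:
        for a, b in zip(group_ws[:-1], group_ws[1:]):
            if b.lo < a.hi - 1e-9:
                raise ValueError("overlapping windows")
    evaluator = DesignEvaluator(cset, design, block_diagonal=block_diagonal)
    base_times = [np.asarray(t, float) for t in ws.times]
    obj_opt = evaluator.objective(base_times)
    lo_list = [np.array([w.lo for w in g]) for g in ws.windows]
    hi_list = [np.array([w.hi for w in g]) for g in ws.windows]
    eff = _joint_efficiency(evaluator, lo_list, hi_list, design.constraints,
                            np.random.default_rng(seed), n_mc, obj_opt)
    return {
        "min": float(eff.min()),
        "percentile": float(np.percentile(eff, percentile)),
        "mean": float(eff.mean()),
        "n_mc": int(n_mc),
    }
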