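"""Population Fisher information matrix (first-order approximation) and
derived design metrics (expected SE/%RSE, D-criterion, efficiency, compound
robust objective).

For one subject sampled at times ``t`` the first-order marginal of the
nonlinear mixed-effects model is::

    E[y] ~= f(theta),   Var[y] ~= A Omega A' + R

where ``A = df/deta`` at ``eta = 0`` (log-normal effects: A_j = p_j*df/dp_j)
and ``R = diag(sigma_add^2 + sigma_prop^2 * f^2)``.  The information for the
estimated parameter vector ``xi`` (free fixed effects, then free variance
components on the variance/covariance scale) is assembled from the usual
Gaussian blocks::

    M[i,j] = dE_i' V^-1 dE_j + 1/2 tr(V^-1 dV_i V^-1 dV_j)

The full matrix (including dV/dtheta and the fixed-effect/variance cross
block) is the default; ``block_diagonal=True`` drops dV/dtheta, which
reproduces the simpler block-diagonal first-order FIM that some design tools
use.  Group information is additive over independent subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .population import CompetingModelSet, PopulationModel
from .structural import AS_TO_DHA, CovariateProfile

_FD_REL = 1e-5  # relative central-difference step for dV/dtheta


# ---------------------------------------------------------------------------
# designs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignConstraints:
    """Feasibility constraints on a sampling schedule (hours)."""

    min_spacing: float = 0.25
    horizon: float = 24.0
    t_min: float = 1.0 / 60.0

    def __post_init__(self):
        if self.min_spacing <= 0:
            raise ValueError("min_spacing must be positive")
        if self.horizon <= self.t_min:
            raise ValueError("horizon must exceed the earliest allowed time")

    def check_times(self, times) -> None:
        t = np.asarray(times, dtype=float)
        if t.size == 0:
            raise ValueError("a group needs at least one sampling time")
        if np.any(np.diff(t) < 0):
            raise ValueError("sampling times must be sorted")
        if t[0] < self.t_min or t[-1] > self.horizon:
            raise ValueError("sampling times outside the design horizon")
        if t.size > 1 and np.min(np.diff(t)) < self.min_spacing - 1e-9:
            raise ValueError("sampling times closer than the minimum spacing")


@dataclass
class Group:
    """One design group: subjects sharing a schedule and covariate profile.

    ``covariates`` lists representative profiles (subjects are split evenly
    across them when computing the group FIM); ``cohort`` optionally carries
    the stochastic covariate sampler used by the trial simulator.
    """

    n_subjects: int
    times: np.ndarray
    covariates: list = field(default_factory=lambda: [CovariateProfile(weight=50.0)])
    dose_mg_per_kg: float = 4.0
    apply_scaling: bool = False
    as_to_dha: bool = True
    name: str = ""
    cohort: object = None

    def __post_init__(self):
        self.times = np.sort(np.asarray(self.times, dtype=float))
        if self.n_subjects <= 0:
            raise ValueError("group size must be positive")

    def dose_for(self, weight) -> np.ndarray:
        d = self.dose_mg_per_kg * np.asarray(weight, dtype=float)
        return d * (AS_TO_DHA if self.as_to_dha else 1.0)


@dataclass
class Design:
    groups: list
    constraints: DesignConstraints = field(default_factory=DesignConstraints)

    def __post_init__(self):
        for g in self.groups:
            self.constraints.check_times(g.times)

    @property
    def n_subjects(self) -> int:
        return sum(g.n_subjects for g in self.groups)

    def with_times(self, times_per_group) -> "Design":
        groups = []
        for g, t in zip(self.groups, times_per_group):
            g2 = Group(
                n_subjects=g.n_subjects, times=np.asarray(t, float),
                covariates=g.covariates, dose_mg_per_kg=g.dose_mg_per_kg,
                apply_scaling=g.apply_scaling, as_to_dha=g.as_to_dha,
                name=g.name, cohort=g.cohort,
            )
            groups.append(g2)
        return Design(groups=groups, constraints=self.constraints)


# ---------------------------------------------------------------------------
# estimated-parameter bookkeeping
# ---------------------------------------------------------------------------

def free_parameters(pm: PopulationModel):
    """Labels, kinds and reference values of the estimated parameters.

    Order: free fixed effects, then free BSV variances (omega^2), free
    covariances, then free residual variances (sigma^2).  %RSEs for variance
    components are reported on this variance/covariance scale.
    """
    names = pm.param_names
    labels, kinds, values = [], [], []
    for j, n in enumerate(names):
        if not pm.fixed_theta[j]:
            labels.append(n)
            kinds.append(("theta", j))
            values.append(pm.theta[j])
    for j, n in enumerate(names):
        if pm.est_om_diag[j]:
            labels.append(f"om2_{n}")
            kinds.append(("om2", j))
            values.append(pm.omega[j, j])
    for a, b in pm.est_om_offdiag:
        i, j = names.index(a), names.index(b)
        labels.append(f"om_{a}_{b}")
        kinds.append(("om", (i, j)))
        values.append(pm.omega[i, j])
    if pm.est_sigma_add:
        labels.append("sig2_add")
        kinds.append(("sig2_add", None))
        values.append(pm.sigma_add**2)
    if pm.est_sigma_prop:
        labels.append("sig2_prop")
        kinds.append(("sig2_prop", None))
        values.append(pm.sigma_prop**2)
    return labels, kinds, np.array(values, dtype=float)


@dataclass
class FIMResult:
    """Information matrix plus derived precision metrics."""

    matrix: np.ndarray
    param_labels: list
    param_values: np.ndarray
    invertible: bool = True

    def __post_init__(self):
        self.matrix = 0.5 * (self.matrix + self.matrix.T)
        sign, ld = np.linalg.slogdet(self.matrix)
        if sign <= 0:
            self.invertible = False
            self.logdet = -np.inf
            self.expected_se = np.full(self.p, np.nan)
        else:
            self.logdet = ld
            try:
                cov = np.linalg.inv(self.matrix)
                d = np.diag(cov)
                if np.any(d <= 0):
                    raise np.linalg.LinAlgError
                self.expected_se = np.sqrt(d)
            except np.linalg.LinAlgError:
                self.invertible = False
                self.expected_se = np.full(self.p, np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            self.expected_rse_pct = 100.0 * self.expected_se / np.abs(self.param_values)

    @property
    def p(self) -> int:
        return self.matrix.shape[0]

    def rse_dict(self) -> dict:
        return dict(zip(self.param_labels, self.expected_rse_pct))


# ---------------------------------------------------------------------------
# batched FIM core
# ---------------------------------------------------------------------------

def _variance(pm, A, f):
    v = np.einsum("...ni,ij,...mj->...nm", A, pm.omega, A)
    n = f.shape[-1]
    idx = np.arange(n)
    # tiny floor keeps V invertible when a sample lands before the absorption
    # lag (f = 0): such an observation contributes no information at all
    # rather than making the whole design singular
    v[..., idx, idx] += pm.sigma_add**2 + pm.sigma_prop**2 * f**2 + 1e-10
    return v


def _mean_and_A(pm, scale, dose, times):
    # conc_grad broadcasts theta (q,) against times (..., n) -> f (..., n), g (..., n, q)
    th = pm.theta * scale
    f, g = pm.structural.conc_grad(th, dose, times)
    A = g * th
    return f, g, A


def fim_batch(pm: PopulationModel, times: np.ndarray, dose: float,
              scale=None, block_diagonal: bool = False) -> np.ndarray:
    """Per-subject FIMs for a batch of candidate schedules.

    ``times`` has shape (m, n); returns (m, p, p).  ``scale`` is the
    covariate multiplier on theta (identity when None); sensitivities are
    reported with respect to the reference (population) parameters.
    """
    times = np.atleast_2d(np.asarray(times, dtype=float))
    q = pm.structural.n_params
    scale = np.ones(q) if scale is None else np.asarray(scale, dtype=float)
    labels, kinds, _ = free_parameters(pm)
    p = len(labels)
    m, n = times.shape

    f, g, A = _mean_and_A(pm, scale, dose, times)
    V = _variance(pm, A, f)
    Vinv = np.linalg.inv(V)

    dE = np.zeros((m, n, p))
    dV = np.zeros((m, p, n, n))
    idx = np.arange(n)
    for ip, (kind, info) in enumerate(kinds):
        if kind == "theta":
            j = info
            dE[..., ip] = g[..., j] * scale[j]
            if not block_diagonal:
                h = _FD_REL * pm.theta[j]
                for sgn in (+1.0, -1.0):
                    th = pm.theta.copy()
                    th[j] += sgn * h
                    pmj = pm.with_theta(th)
                    fj, _, Aj = _mean_and_A(pmj, scale, dose, times)
                    dV[:, ip] += sgn * _variance(pm, Aj, fj) / (2.0 * h)
        elif kind == "om2":
            aj = A[..., info]
            dV[:, ip] = aj[:, :, None] * aj[:, None, :]
        elif kind == "om":
            i, j = info
            ai, aj = A[..., i], A[..., j]
            dV[:, ip] = ai[:, :, None] * aj[:, None, :] + aj[:, :, None] * ai[:, None, :]
        elif kind == "sig2_add":
            dV[:, ip, idx, idx] = 1.0
        elif kind == "sig2_prop":
            dV[:, ip, idx, idx] = f**2
    M = np.einsum("mnp,mnk,mkq->mpq", dE, Vinv, dE)
    W = np.einsum("mab,mpbc->mpac", Vinv, dV)
    M += 0.5 * np.einsum("mpab,mqba->mpq", W, W)
    return M


def _group_fim_batch(pm, group: Group, times, block_diagonal=False) -> np.ndarray:
    """Mean per-subject FIM over the group's representative profiles,
    times the group size."""
    acc = None
    for cov in group.covariates:
        scale = (
            pm.structural.scale_factors(cov.weight, cov.age, pm.scaling)
            if group.apply_scaling else None
        )
        dose = float(group.dose_for(cov.weight))
        M = fim_batch(pm, times, dose, scale=scale, block_diagonal=block_diagonal)
        acc = M if acc is None else acc + M
    return group.n_subjects * acc / len(group.covariates)


def individual_fim(pm: PopulationModel, cov: CovariateProfile, dose: float,
                   times, apply_scaling: bool = False,
                   block_diagonal: bool = False) -> FIMResult:
    """FIM for a single subject sampled at ``times`` (dose in mg DHA-eq)."""
    scale = (
        pm.structural.scale_factors(cov.weight, cov.age, pm.scaling)
        if apply_scaling else None
    )
    labels, _, values = free_parameters(pm)
    M = fim_batch(pm, np.atleast_2d(times), dose, scale=scale,
                  block_diagonal=block_diagonal)[0]
    return FIMResult(matrix=M, param_labels=labels, param_values=values)


def population_fim(pm: PopulationModel, design: Design,
                   block_diagonal: bool = False) -> FIMResult:
    """Population FIM: sum of group FIMs weighted by group size."""
    labels, _, values = free_parameters(pm)
    M = sum(
        _group_fim_batch(pm, g, np.atleast_2d(g.times), block_diagonal)[0]
        for g in design.groups
    )
    return FIMResult(matrix=M, param_labels=labels, param_values=values)


# ---------------------------------------------------------------------------
# design metrics
# ---------------------------------------------------------------------------

def d_criterion(fim: FIMResult) -> float:
    """log det of the information matrix; -inf for a non-PD matrix."""
    return fim.logdet


def efficiency(candidate: FIMResult, reference: FIMResult) -> float:
    """(det candidate / det reference)^(1/p); 0.8 = 20% efficiency loss."""
    if candidate.param_labels != reference.param_labels:
        raise ValueError("designs evaluate different parameterisations")
    if not (np.isfinite(candidate.logdet) and np.isfinite(reference.logdet)):
        return 0.0 if candidate.logdet < reference.logdet else np.inf
    return float(np.exp((candidate.logdet - reference.logdet) / candidate.p))


def compound_objective(cset: CompetingModelSet, design: Design,
                       block_diagonal: bool = False) -> float:
    """Weighted sum of normalised log-determinants over competing models."""
    total = 0.0
    for pm, w in cset.members:
        fr = population_fim(pm, design, block_diagonal=block_diagonal)
        if not np.isfinite(fr.logdet):
            return -np.inf
        total += w * fr.logdet / fr.p
    return total


# ---------------------------------------------------------------------------
# batched compound evaluator shared by the search and window modules
# ---------------------------------------------------------------------------

class DesignEvaluator:
    """Evaluates the compound objective for many candidate schedules at once.

    Caches per-member, per-group FIMs at the current times so coordinate
    exchange and window Monte-Carlo only recompute the group being varied.
    """

    def __init__(self, cset: CompetingModelSet, design: Design,
                 block_diagonal: bool = False):
        self.cset = cset
        self.design = design
        self.block_diagonal = block_diagonal
        self.p = [len(free_parameters(pm)[0]) for pm in cset.models]

    def group_fims(self, member: int, group: int, times_batch) -> np.ndarray:
        pm = self.cset.models[member]
        return _group_fim_batch(pm, self.design.groups[group],
                                np.atleast_2d(np.asarray(times_batch, float)),
                                self.block_diagonal)

    def objective(self, times_per_group) -> float:
        return float(self.objective_batch([np.atleast_2d(t) for t in times_per_group])[0])

    def objective_batch(self, times_batches) -> np.ndarray:
        """``times_batches``: one (m, n_g) array per group (same m)."""
        m = np.atleast_2d(times_batches[0]).shape[0]
        out = np.zeros(m)
        w = self.cset.weights
        for im in range(len(self.cset)):
            M = None
            for ig in range(len(self.design.groups)):
                tb = np.atleast_2d(times_batches[ig])
                if tb.shape[0] == 1 and m > 1:
                    Mg = self.group_fims(im, ig, tb)
                    Mg = np.broadcast_to(Mg, (m,) + Mg.shape[1:])
                else:
                    Mg = self.group_fims(im, ig, tb)
                M = Mg.copy() if M is None else M + Mg
            sign, ld = np.linalg.slogdet(M)
            ld = np.where(sign > 0, ld, -np.inf)
            out = out + w[im] * ld / self.p[im]
        return out
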