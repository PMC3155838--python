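"""Population PK models: fixed effects, between-subject variability, residual
error, and the weighted registry of competing models used for robust design.

Random effects are log-normal: parameter_i = theta_i * exp(eta_i) with
eta ~ MVN(0, Omega) on the log scale.  Between-subject variability (BSV) is
entered as CV% with pairwise correlations and mapped to Omega by the
first-order convention omega_i = CV_i/100 (an exact log-normal inversion is
available via ``cv_mapping="exact"``).  The residual model is combined:
y = f*(1 + eps_prop) + eps_add.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .structural import CovariateProfile, ScalingConfig, StructuralModel


def _corr_key(a: str, b: str) -> tuple:
    return tuple(sorted((a, b)))


@dataclass
class PopulationModel:
    """A structural model plus its population-level statistical model.

    ``fixed_theta``/``est_om_diag``/``est_om_offdiag``/``est_sigma_*`` record
    which components are estimated; fixed components are excluded from the
    Fisher information matrix and held at their values during fitting.
    ``omega`` is the full log-scale covariance over all structural parameters
    (zero rows/columns mean "no random effect on this parameter").
    """

    structural: StructuralModel
    theta: np.ndarray
    omega: np.ndarray
    sigma_prop: float = 0.0
    sigma_add: float = 0.0
    fixed_theta: np.ndarray = None
    est_om_diag: np.ndarray = None
    est_om_offdiag: tuple = ()
    est_sigma_prop: bool = True
    est_sigma_add: bool = False
    scaling: ScalingConfig = field(default_factory=ScalingConfig)
    label: str = ""

    def __post_init__(self):
        q = self.structural.n_params
        self.theta = np.asarray(self.theta, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        if self.theta.shape != (q,):
            raise ValueError(f"theta must have length {q}")
        if self.omega.shape != (q, q):
            raise ValueError(f"omega must be {q}x{q}")
        if not np.allclose(self.omega, self.omega.T, atol=1e-12):
            raise ValueError("omega must be symmetric")
        eig = np.linalg.eigvalsh(self.omega)
        if eig.min() < -1e-10:
            raise ValueError("omega must be positive semi-definite")
        if self.sigma_prop < 0 or self.sigma_add < 0:
            raise ValueError("residual SDs must be non-negative")
        if self.sigma_prop == 0 and self.sigma_add == 0:
            raise ValueError("at least one residual component must be non-zero")
        if self.fixed_theta is None:
            self.fixed_theta = np.zeros(q, dtype=bool)
        else:
            self.fixed_theta = np.asarray(self.fixed_theta, dtype=bool)
        if self.est_om_diag is None:
            self.est_om_diag = np.diag(self.omega) > 0
        else:
            self.est_om_diag = np.asarray(self.est_om_diag, dtype=bool)
        self.est_om_offdiag = tuple(tuple(sorted(p)) for p in self.est_om_offdiag)

    # -- convenience ---------------------------------------------------
    @property
    def param_names(self) -> tuple:
        return self.structural.param_names

    def theta_dict(self) -> dict:
        return dict(zip(self.param_names, self.theta))

    def omega_cv(self) -> tuple:
        """Round-trip Omega back to user-facing (CV% dict, correlation dict)."""
        names = self.param_names
        sd = np.sqrt(np.diag(self.omega))
        cvs = {n: 100.0 * sd[i] for i, n in enumerate(names) if sd[i] > 0}
        corrs = {}
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if self.omega[i, j] != 0.0:
                    corrs[_corr_key(names[i], names[j])] = self.omega[i, j] / (sd[i] * sd[j])
        return cvs, corrs

    def with_theta(self, theta, label_suffix: str = "") -> "PopulationModel":
        out = replace(self, theta=np.asarray(theta, dtype=float))
        if label_suffix:
            out.label = f"{self.label}{label_suffix}"
        return out


def build_population_model(
    structural: StructuralModel,
    theta: dict,
    bsv_cv: dict = None,
    corr: dict = None,
    sigma_prop: float = 0.0,
    sigma_add: float = 0.0,
    fixed_theta: tuple = (),
    fixed_bsv: tuple = (),
    est_corr: tuple = None,
    est_sigma_prop: bool = True,
    est_sigma_add: bool = False,
    scaling: ScalingConfig = None,
    cv_mapping: str = "linear",
    label: str = "",
) -> PopulationModel:
    """Assemble a PopulationModel from named Table-style entries.

    ``bsv_cv`` maps parameter names to BSV in CV%; ``corr`` maps
    ``"name1,name2"`` (or 2-tuples) to correlations.  ``fixed_theta`` and
    ``fixed_bsv`` name components excluded from estimation; ``est_corr``
    names the correlation pairs that are estimated (default: all entered).
    """
    names = structural.param_names
    unknown = set(theta) - set(names)
    if unknown:
        raise ValueError(f"unknown parameter(s) {sorted(unknown)}")
    missing = set(names) - set(theta)
    if missing:
        raise ValueError(f"missing parameter(s) {sorted(missing)}")
    th = np.array([float(theta[n]) for n in names])

    bsv_cv = dict(bsv_cv or {})
    unknown = set(bsv_cv) - set(names)
    if unknown:
        raise ValueError(f"BSV given for unknown parameter(s) {sorted(unknown)}")
    if cv_mapping == "linear":
        sd = {n: cv / 100.0 for n, cv in bsv_cv.items()}
    elif cv_mapping == "exact":
        sd = {n: np.sqrt(np.log1p((cv / 100.0) ** 2)) for n, cv in bsv_cv.items()}
    else:
        raise ValueError(f"unknown cv_mapping {cv_mapping!r}")

    q = len(names)
    omega = np.zeros((q, q))
    for n, s in sd.items():
        omega[names.index(n), names.index(n)] = s * s

    entered_corr = {}
    for key, rho in (corr or {}).items():
        pair = tuple(key.split(",")) if isinstance(key, str) else tuple(key)
        if len(pair) != 2 or any(p not in names for p in pair):
            raise ValueError(f"bad correlation key {key!r}")
        if not -1.0 <= rho <= 1.0:
            raise ValueError(f"correlation {key} = {rho} outside [-1, 1]")
        a, b = pair
        if a not in sd or b not in sd:
            raise ValueError(f"correlation {key} given but a BSV is missing")
        i, j = names.index(a), names.index(b)
        omega[i, j] = omega[j, i] = rho * sd[a] * sd[b]
        entered_corr[_corr_key(a, b)] = rho

    eig = np.linalg.eigvalsh(omega)
    if eig.min() < -1e-10:
        bad = ", ".join(f"{a},{b}" for a, b in entered_corr)
        raise ValueError(f"omega not positive semi-definite; check correlation(s) {bad}")

    fixed = np.zeros(q, dtype=bool)
    for n in fixed_theta:
        fixed[names.index(n)] = True
    est_diag = np.array([n in bsv_cv and n not in fixed_bsv for n in names])
    if est_corr is None:
        est_od = tuple(entered_corr)
    else:
        est_od = tuple(
            _corr_key(*((k.split(",")) if isinstance(k, str) else k)) for k in est_corr
        )
    return PopulationModel(
        structural=structural,
        theta=th,
        omega=omega,
        sigma_prop=sigma_prop,
        sigma_add=sigma_add,
        fixed_theta=fixed,
        est_om_diag=est_diag,
        est_om_offdiag=est_od,
        est_sigma_prop=est_sigma_prop,
        est_sigma_add=est_sigma_add,
        scaling=scaling or ScalingConfig(),
        label=label,
    )


# ---------------------------------------------------------------------------
# competing model sets (robust design)
# ---------------------------------------------------------------------------

@dataclass
class CompetingModelSet:
    """Weighted collection of candidate population models.

    The robust D-criterion optimises the weighted sum of normalised
    log-determinants over the members.  Weights are positive and sum to 1.
    """

    members: list            # list of (PopulationModel, weight)
    provenance: list = None  # parallel tags: central / ci_lower / ci_upper

    def __post_init__(self):
        w = np.array([wt for _, wt in self.members], dtype=float)
        if len(w) == 0 or np.any(w <= 0):
            raise ValueError("weights must be positive")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if self.provenance is None:
            self.provenance = ["central"] * len(self.members)

    def __len__(self):
        return len(self.members)

    @property
    def weights(self) -> np.ndarray:
        return np.array([wt for _, wt in self.members])

    @property
    def models(self) -> list:
        return [m for m, _ in self.members]


def build_competing_set(variants, central_weight: float = 0.95) -> CompetingModelSet:
    """Build the 3-point robust set: per structural variant, the central
    estimates plus the lower and upper 95%-CI parameter sets.

    ``variants`` is a list of ``(PopulationModel, ci_bounds)`` where
    ``ci_bounds`` maps parameter names to ``(lower, upper)``; parameters
    without an entry (e.g. a fixed lag) stay at their central value.  The
    central member of each variant receives ``central_weight/S`` and each CI
    member ``(1-central_weight)/(2S)``, S the number of variants.  With
    ``central_weight=1`` only the central members are kept.
    """
    if not 0.0 < central_weight <= 1.0:
        raise ValueError("central_weight must lie in (0, 1]")
    s = len(variants)
    if s == 0:
        raise ValueError("at least one variant required")
    members, tags = [], []
    w_c = central_weight / s
    w_b = (1.0 - central_weight) / (2.0 * s)
    for pm, ci in variants:
        ci = ci or {}
        for name, (lo, hi) in ci.items():
            if lo <= 0 or hi <= 0:
                raise ValueError(f"CI bounds for {name} must be positive")
        members.append((pm, w_c))
        tags.append("central")
        if w_b > 0.0:
            for which, tag in ((0, "ci_lower"), (1, "ci_upper")):
                th = dict(pm.theta_dict())
                for name, bounds in ci.items():
                    th[name] = bounds[which]
                theta = np.array([th[n] for n in pm.param_names])
                members.append((pm.with_theta(theta, f"_{tag}"), w_b))
                tags.append(tag)
    return CompetingModelSet(members=members, provenance=tags)


def individual_parameters(
    pm: PopulationModel,
    cov: CovariateProfile,
    eta: np.ndarray,
    apply_scaling: bool = False,
) -> np.ndarray:
    """Individual parameters: covariate scaling first, then exp(eta)."""
    eta = np.asarray(eta, dtype=float)
    if eta.shape[-1] != pm.structural.n_params:
        raise ValueError("eta dimension must match the parameter count")
    th = pm.theta
    if apply_scaling:
        th = th * pm.structural.scale_factors(cov.weight, cov.age, pm.scaling)
    return th * np.exp(eta)
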