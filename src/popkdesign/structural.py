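"""Closed-form structural PK models for DHA after oral artesunate.

Two one-compartment disposition models with first-order elimination are
supported, both with an optional absorption lag time:

* Bateman: first-order absorption with rate ``ka`` distinct from the
  elimination rate ``k = CL/F / (V/F)``::

      C(t) = D*ka / (V*(ka - k)) * (exp(-k*tau) - exp(-ka*tau)),  tau = t - tlag

* Dost: the analytic limit ``ka -> k`` (a single common rate constant)::

      C(t) = (D/V) * k * tau * exp(-k*tau)

Concentrations are mg/L, times hours, doses mg (DHA-equivalents), volumes L,
clearances L/h.  All functions are numpy-vectorised and broadcast parameters
against time, which the FIM engine and the mixed-effects estimator rely on
for batched evaluation.

The Bateman difference of exponentials is evaluated through
``phi(x) = -expm1(-x)/x`` which is numerically stable for ``ka`` arbitrarily
close to ``k``; at exact equality the Dost limit is returned, so no caller
ever needs to guard the degenerate case.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

# Molar masses (g/mol): oral artesunate is assumed fully converted to DHA, so a
# dose of artesunate corresponds to dose * MW_DHA/MW_AS of DHA-equivalents.
MW_ARTESUNATE = 384.42
MW_DHA = 284.35
AS_TO_DHA = MW_DHA / MW_ARTESUNATE


# ---------------------------------------------------------------------------
# numerically stable helpers
# ---------------------------------------------------------------------------

def _phi(x):
    """(1 - exp(-x)) / x, with phi(0) = 1."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    nz = x != 0.0
    out[nz] = -np.expm1(-x[nz]) / x[nz]
    return out


def _dphi(x):
    """Derivative of _phi: (exp(-x)*(1+x) - 1) / x**2, series near 0."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-3
    xs = x[small]
    out[small] = -0.5 + xs / 3.0 - xs**2 / 8.0 + xs**3 / 30.0
    xl = x[~small]
    out[~small] = (np.exp(-xl) * (1.0 + xl) - 1.0) / xl**2
    return out


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BatemanParams:
    """Bateman model parameters (ka 1/h, CL/F L/h, V/F L, tlag h)."""

    ka: float
    cl_f: float
    v_f: float
    tlag: float = 0.0
    f_rel: float = 1.0

    def __post_init__(self):
        if self.ka <= 0 or self.cl_f <= 0 or self.v_f <= 0:
            raise ValueError("ka, CL/F and V/F must be strictly positive")
        if self.tlag < 0:
            raise ValueError("tlag must be non-negative")

    @property
    def k(self) -> float:
        return self.cl_f / self.v_f

    def as_array(self) -> np.ndarray:
        return np.array([self.ka, self.cl_f, self.v_f, self.tlag])


@dataclass(frozen=True)
class DostParams:
    """Dost model parameters (common rate k 1/h, V/F L, tlag h)."""

    k: float
    v_f: float
    tlag: float = 0.0
    f_rel: float = 1.0

    def __post_init__(self):
        if self.k <= 0 or self.v_f <= 0:
            raise ValueError("k and V/F must be strictly positive")
        if self.tlag < 0:
            raise ValueError("tlag must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.k, self.v_f, self.tlag])


@dataclass(frozen=True)
class CovariateProfile:
    """Subject-level covariates used for dosing and allometric scaling."""

    weight: float
    age: float = 30.0
    population_label: str = "non_pregnant_adult"

    def __post_init__(self):
        if self.weight <= 0:
            raise ValueError("weight must be strictly positive")
        if self.age < 0:
            raise ValueError("age must be non-negative")


@dataclass(frozen=True)
class ScalingConfig:
    """Allometric scaling and clearance-maturation settings.

    CL/F scales as ``(weight/w_ref)**exp_cl * MF(age)`` and V/F as
    ``(weight/w_ref)**exp_v``; absorption parameters are not scaled.
    The maturation multiplier MF is 1 for adults and rises from 0 with age:

    * ``exponential``: ``MF = 1 - exp(-k_mat*age)`` (age in years)
    * ``hill``: ``MF = age**g / (tm50**g + age**g)``
    * ``none``: ``MF = 1``
    """

    w_ref: float = 50.0
    exp_cl: float = 0.75
    exp_v: float = 1.0
    maturation_form: str = "exponential"
    k_mat: float = 2.0
    hill_tm50: float = 0.5
    hill_gamma: float = 3.0

    def __post_init__(self):
        if not (0.0 < self.exp_cl < 2.0 and 0.0 < self.exp_v < 2.0):
            raise ValueError("allometric exponents must lie in (0, 2)")
        if self.maturation_form not in ("exponential", "hill", "none"):
            raise ValueError(f"unknown maturation form {self.maturation_form!r}")
        if self.w_ref <= 0:
            raise ValueError("reference weight must be positive")


def maturation_multiplier(age, cfg: ScalingConfig):
    """Age-dependent multiplier on CL/F, in (0, 1]."""
    age = np.asarray(age, dtype=float)
    if cfg.maturation_form == "none":
        return np.ones_like(age)
    if cfg.maturation_form == "exponential":
        return -np.expm1(-cfg.k_mat * age)
    g = cfg.hill_gamma
    return age**g / (cfg.hill_tm50**g + age**g)


# ---------------------------------------------------------------------------
# concentration functions (array core)
# ---------------------------------------------------------------------------

def bateman_concentration_arr(ka, cl_f, v_f, tlag, dose, t):
    """Bateman concentration; broadcasts all arguments.

    Stable for ka arbitrarily close to k = cl_f/v_f (expm1-based form); at
    exact equality the Dost limit is used.
    """
    ka, cl_f, v_f, tlag, dose, t = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (ka, cl_f, v_f, tlag, dose, t))
    )
    tau = np.maximum(t - tlag, 0.0)
    k = cl_f / v_f
    delta = ka - k
    x = delta * tau
    small = np.abs(x) < 1e-3
    # near ka == k the difference of exponentials cancels: use the stable
    # phi form C = (D*ka*tau/V) * exp(-k*tau) * phi(x), phi(0)=1 (Dost);
    # elsewhere the plain two-exponential form is exact and overflow-free
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        c_small = dose * ka * tau / v_f * np.exp(-k * tau) * _phi(x)
        d_safe = np.where(small, 1.0, delta)
        c_big = dose * ka / (v_f * d_safe) * (np.exp(-k * tau) - np.exp(-ka * tau))
    return np.where(small, c_small, c_big)


def bateman_concentration_grad_arr(ka, cl_f, v_f, tlag, dose, t):
    """Concentration and analytic gradient wrt (ka, cl_f, v_f, tlag).

    Returns ``(c, g)`` with ``g`` stacked on the last axis in parameter order.
    The gradient wrt tlag is 0 for t <= tlag (one-sided at the kink).
    """
    ka, cl_f, v_f, tlag, dose, t = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (ka, cl_f, v_f, tlag, dose, t))
    )
    tau = np.maximum(t - tlag, 0.0)
    k = cl_f / v_f
    delta = ka - k
    x = delta * tau
    small = np.abs(x) < 1e-3
    ek = np.exp(-k * tau)

    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        # stable phi-form branch for the near-degenerate region
        ph, dph = _phi(x), _dphi(x)
        base = dose * tau / v_f * ek          # = C / (ka*phi)
        c_s = base * ka * ph
        dka_s = base * (ph + ka * tau * dph)
        dk_s = -base * ka * tau * (ph + dph)  # partial wrt k at fixed ka
        dtau_s = dose * ka / v_f * ek * (ph * (1.0 - k * tau) + x * dph)

        # plain two-exponential branch elsewhere (exact, overflow-free)
        d_safe = np.where(small, 1.0, delta)
        ea = np.exp(-ka * tau)
        diff = ek - ea
        b = dose / (v_f * d_safe)
        c_b = b * ka * diff
        dka_b = -dose * diff * k / (v_f * d_safe**2) + b * ka * tau * ea
        dk_b = dose * ka / v_f * (diff / d_safe**2 - tau * ek / d_safe)
        dtau_b = b * ka * (-k * ek + ka * ea)

    c = np.where(small, c_s, c_b)
    dc_dka = np.where(small, dka_s, dka_b)
    dc_dk = np.where(small, dk_s, dk_b)
    dc_dtau = np.where(small, dtau_s, dtau_b)
    dc_dcl = dc_dk / v_f
    dc_dv = -c / v_f + dc_dk * (-cl_f / v_f**2)
    dc_dtlag = np.where(tau > 0.0, -dc_dtau, 0.0)
    return c, np.stack([dc_dka, dc_dcl, dc_dv, dc_dtlag], axis=-1)


def dost_concentration_arr(k, v_f, tlag, dose, t):
    """Dost concentration; broadcasts all arguments."""
    k, v_f, tlag, dose, t = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (k, v_f, tlag, dose, t))
    )
    tau = np.maximum(t - tlag, 0.0)
    return dose / v_f * k * tau * np.exp(-k * tau)


def dost_concentration_grad_arr(k, v_f, tlag, dose, t):
    """Concentration and analytic gradient wrt (k, v_f, tlag)."""
    k, v_f, tlag, dose, t = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (k, v_f, tlag, dose, t))
    )
    tau = np.maximum(t - tlag, 0.0)
    ek = np.exp(-k * tau)
    c = dose / v_f * k * tau * ek
    dc_dk = dose / v_f * tau * ek * (1.0 - k * tau)
    dc_dv = -c / v_f
    dc_dtlag = np.where(tau > 0.0, -dose / v_f * k * ek * (1.0 - k * tau), 0.0)
    return c, np.stack([dc_dk, dc_dv, dc_dtlag], axis=-1)


# ---------------------------------------------------------------------------
# model objects (uniform interface used by the FIM engine and estimator)
# ---------------------------------------------------------------------------

class StructuralModel:
    """Interface: ``param_names``, ``conc``, ``conc_grad``, ``scale_factors``.

    ``theta`` arguments are arrays whose last axis indexes the parameters in
    ``param_names`` order; every other axis broadcasts against ``t`` after a
    keepdims slice, so per-subject parameter arrays of shape (n, 1, q) work
    against time arrays of shape (n, m).
    """

    param_names: tuple
    name: str

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def _cols(self, theta):
        theta = np.asarray(theta, dtype=float)
        return [theta[..., j] for j in range(self.n_params)]

    def conc(self, theta, dose, t):
        raise NotImplementedError

    def conc_grad(self, theta, dose, t):
        raise NotImplementedError

    def scale_factors(self, weight, age, cfg: ScalingConfig):
        """Multiplicative covariate factors per parameter (last axis)."""
        raise NotImplementedError

    def index(self, name: str) -> int:
        return self.param_names.index(name)


class BatemanModel(StructuralModel):
    param_names = ("ka", "cl_f", "v_f", "tlag")
    name = "bateman"

    def conc(self, theta, dose, t):
        ka, cl, v, tl = self._cols(theta)
        return bateman_concentration_arr(ka, cl, v, tl, dose, t)

    def conc_grad(self, theta, dose, t):
        ka, cl, v, tl = self._cols(theta)
        return bateman_concentration_grad_arr(ka, cl, v, tl, dose, t)

    def scale_factors(self, weight, age, cfg: ScalingConfig):
        weight = np.asarray(weight, dtype=float)
        age = np.asarray(age, dtype=float)
        one = np.ones(np.broadcast_shapes(weight.shape, age.shape))
        s_cl = (weight / cfg.w_ref) ** cfg.exp_cl * maturation_multiplier(age, cfg)
        s_v = (weight / cfg.w_ref) ** cfg.exp_v * one
        return np.stack([one, s_cl * one, s_v, one], axis=-1)


class DostModel(StructuralModel):
    param_names = ("k", "v_f", "tlag")
    name = "dost"

    def conc(self, theta, dose, t):
        k, v, tl = self._cols(theta)
        return dost_concentration_arr(k, v, tl, dose, t)

    def conc_grad(self, theta, dose, t):
        k, v, tl = self._cols(theta)
        return dost_concentration_grad_arr(k, v, tl, dose, t)

    def scale_factors(self, weight, age, cfg: ScalingConfig):
        # only V/F is scalable for the single-rate model
        weight = np.asarray(weight, dtype=float)
        age = np.asarray(age, dtype=float)
        one = np.ones(np.broadcast_shapes(weight.shape, age.shape))
        s_v = (weight / cfg.w_ref) ** cfg.exp_v * one
        return np.stack([one, s_v, one], axis=-1)


BATEMAN = BatemanModel()
DOST = DostModel()


# ---------------------------------------------------------------------------
# dataclass-level conveniences
# ---------------------------------------------------------------------------

def bateman_concentration(p: BatemanParams, dose, t):
    """Concentration (mg/L) for a dose (mg DHA-equivalents) at time t (h)."""
    return bateman_concentration_arr(p.ka, p.cl_f, p.v_f, p.tlag, p.f_rel * np.asarray(dose, float), t)


def dost_concentration(p: DostParams, dose, t):
    return dost_concentration_arr(p.k, p.v_f, p.tlag, p.f_rel * np.asarray(dose, float), t)


def scale_parameters(adult: BatemanParams, cov: CovariateProfile, cfg: ScalingConfig) -> BatemanParams:
    """Allometrically scale CL/F and V/F (with CL maturation); ka, tlag kept."""
    s = BATEMAN.scale_factors(cov.weight, cov.age, cfg)
    return replace(adult, cl_f=adult.cl_f * float(s[..., 1]), v_f=adult.v_f * float(s[..., 2]))


def as_dose_to_dha(dose_mg_as, convert: bool = True):
    """Convert an artesunate dose to DHA-equivalent mg (molar correction)."""
    return np.asarray(dose_mg_as, dtype=float) * (AS_TO_DHA if convert else 1.0)
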