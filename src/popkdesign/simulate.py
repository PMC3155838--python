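"""Virtual cohorts and simulated DHA concentration datasets.

Cohorts emulate the covariate structure assumed for the target populations
of an oral-artesunate PK study:

* non-pregnant adults: log-normal body weights (median 50 kg, CV 15%);
* children: age uniform within the group's age bracket, weight from a linear
  age->weight model (8.0 + 2.5*age kg) with 15% residual CV, truncated to
  3-70 kg;
* pregnant women: normal weights (mean 50 kg, SD 6 kg) truncated positive.

These distribution parameters are package defaults standing in for field
data summaries and are fully configurable.  Dosing is per-kg oral artesunate
(default 4 mg/kg) converted to DHA-equivalents.  Observations follow the
population model: eta ~ MVN(0, Omega) on the log scale, y = f*(1+eps1)+eps2,
with negative simulated concentrations floored at zero and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fim import Design, Group
from .population import PopulationModel
from .structural import CovariateProfile

REQUIRED_COLUMNS = ("ID", "GROUP", "TIME", "DV", "AMT", "WT", "AGE")


@dataclass
class CohortSpec:
    """Sampler for one group's covariates (weights kg, ages years)."""

    population_label: str = "non_pregnant_adult"
    n_subjects: int = 60
    dose_mg_per_kg: float = 4.0
    # adults (log-normal weight)
    weight_median: float = 50.0
    weight_cv: float = 0.15
    adult_age: float = 30.0
    # children (uniform age in bracket, linear age->weight)
    age_range: tuple = (0.25, 2.0)
    wt_intercept: float = 8.0
    wt_slope: float = 2.5
    wt_res_cv: float = 0.15
    wt_bounds: tuple = (3.0, 70.0)
    # pregnant women (truncated normal weight)
    preg_weight_mean: float = 50.0
    preg_weight_sd: float = 6.0
    preg_age: float = 28.0

    def __post_init__(self):
        if self.n_subjects <= 0:
            raise ValueError("cohort must contain at least one subject")
        if self.population_label not in ("non_pregnant_adult", "child", "pregnant"):
            raise ValueError(f"unknown population {self.population_label!r}")


def simulate_cohort(spec: CohortSpec, rng) -> list:
    """Draw covariate profiles; reproducible given the generator state."""
    n = spec.n_subjects
    if spec.population_label == "non_pregnant_adult":
        sdlog = np.sqrt(np.log1p(spec.weight_cv**2))
        w = spec.weight_median * np.exp(rng.normal(0.0, sdlog, n))
        ages = np.full(n, spec.adult_age)
    elif spec.population_label == "child":
        lo, hi = spec.age_range
        ages = rng.uniform(lo, hi, n)
        w = (spec.wt_intercept + spec.wt_slope * ages) * \
            (1.0 + spec.wt_res_cv * rng.standard_normal(n))
        w = np.clip(w, *spec.wt_bounds)
    else:  # pregnant
        w = rng.normal(spec.preg_weight_mean, spec.preg_weight_sd, n)
        while np.any(w <= 1.0):
            w[w <= 1.0] = rng.normal(spec.preg_weight_mean, spec.preg_weight_sd,
                                     int(np.sum(w <= 1.0)))
        ages = np.full(n, spec.preg_age)
    return [
        CovariateProfile(weight=float(wi), age=float(ai),
                         population_label=spec.population_label)
        for wi, ai in zip(w, ages)
    ]


@dataclass
class TrialDataset:
    """Long-format concentration records for one simulated trial.

    ``df`` columns: ID, GROUP, TIME (h), DV (mg/L), AMT (mg DHA-eq), WT, AGE,
    BLQ_FLOOR (simulated value fell below zero and was floored), plus the
    per-group scaling flags needed to refit the data.
    """

    df: pd.DataFrame
    group_scaling: dict = field(default_factory=dict)  # group name -> bool

    def __post_init__(self):
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"dataset missing column(s) {missing}")
        if (self.df["DV"] < 0).any():
            raise ValueError("negative concentrations in dataset")

    @property
    def n_subjects(self) -> int:
        return self.df["ID"].nunique()

    def subject_blocks(self):
        """Yield (group_name, ids, times (nt,), y (ns, nt), dose (ns,),
        wt (ns,), age (ns,)) with one block per design group."""
        for gname, gdf in self.df.groupby("GROUP", sort=False):
            piv = gdf.pivot_table(index="ID", columns="TIME", values="DV", sort=True)
            ids = piv.index.to_numpy()
            times = piv.columns.to_numpy(dtype=float)
            y = piv.to_numpy(dtype=float)
            sub = gdf.drop_duplicates("ID").set_index("ID").loc[ids]
            yield (gname, ids, times, y,
                   sub["AMT"].to_numpy(float), sub["WT"].to_numpy(float),
                   sub["AGE"].to_numpy(float))


def simulate_trial(pm: PopulationModel, design: Design, seed: int = 0,
                   lloq: float = None, omega_scale: float = 1.0,
                   residual: bool = True) -> TrialDataset:
    """Simulate one trial at the design's sampling times.

    Each group uses its ``cohort`` sampler when present, otherwise its
    representative covariate profiles.  ``omega_scale``/``residual`` allow
    switching off between-subject or residual variability for diagnostics.
    """
    rng = np.random.default_rng(seed)
    q = pm.structural.n_params
    omega = pm.omega * omega_scale
    chol = np.linalg.cholesky(omega + 1e-300 * np.eye(q)) if np.any(omega) else None

    records = []
    group_scaling = {}
    sid = 0
    for g in design.groups:
        group_scaling[g.name] = g.apply_scaling
        if g.cohort is not None:
            profiles = simulate_cohort(g.cohort, rng)
        else:
            reps = int(np.ceil(g.n_subjects / len(g.covariates)))
            profiles = (g.covariates * reps)[: g.n_subjects]
        times = np.asarray(g.times, float)
        for cov in profiles:
            sid += 1
            eta = chol @ rng.standard_normal(q) if chol is not None else np.zeros(q)
            th = pm.theta.copy()
            if g.apply_scaling:
                th = th * pm.structural.scale_factors(cov.weight, cov.age, pm.scaling)
            p_ind = th * np.exp(eta)
            dose = float(g.dose_for(cov.weight))
            f = pm.structural.conc(p_ind, dose, times)
            if residual:
                y = f * (1.0 + pm.sigma_prop * rng.standard_normal(times.size)) \
                    + pm.sigma_add * rng.standard_normal(times.size)
            else:
                y = f.copy()
            floored = y < 0.0
            y = np.maximum(y, 0.0)
            for j, t in enumerate(times):
                records.append({
                    "ID": sid, "GROUP": g.name, "TIME": float(t),
                    "DV": float(y[j]), "AMT": dose, "WT": cov.weight,
                    "AGE": cov.age, "BLQ_FLOOR": bool(floored[j]),
                    "BLQ": bool(lloq is not None and y[j] < lloq),
                })
    df = pd.DataFrame.from_records(records)
    return TrialDataset(df=df, group_scaling=group_scaling)
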