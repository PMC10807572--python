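"""Synthetic allo-HSCT cohort generator.

Because the clinical source data are access-restricted, every other module
is exercised on synthetic cohorts that reproduce the statistical structure
the analysis assumes:

* static covariate frequencies of an adult allo-HSCT population
  (median age 54, range 17-76; ~40% related donors; 23% FluTBI
  conditioning; ~22% female-donor/male-recipient pairs);
* biphasic WBC recovery — conditioning aplasia with a nadir of 0.055
  cells/nL on day 8, recovery through ~2.3 (day 20) and ~4.7 (day 30) to a
  peak of 6.0 cells/nL on day 41, then a plateau near 3.9 cells/nL — as a
  log-space piecewise-linear template times lognormal patient noise;
* CsA trough profiles with marginal median 178 ng/mL and 5th/95th
  percentiles 48.0/333.1 ng/mL (a two-piece lognormal, since those printed
  quantiles are asymmetric on the log scale), sampled every 2 days with
  within-patient correlation;
* event times drawn from the transit-delay hazard model itself, with
  day-100 administrative censoring and exponential dropout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import model
from .data import CohortDataset, PatientGrids
from .model import HORIZON, WBC_FLOOR, FinalModelParameters, PopulationReference
from .simulate import _sample_from_cumhaz

__all__ = ["GeneratorConfig", "generate_cohort", "population_reference"]

_Z95 = float(stats.norm.ppf(0.95))  # 1.6449, maps P5/P95 to log-scale sigmas


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults mirror the reference cohort: n = 1479 patients followed for
    100 days. ``wbc_knots`` are (day, cells/nL) template anchors joined
    log-linearly and held flat after the last knot; the day-0 value of 5.0
    is a plausible pre-conditioning count.  ``csa_within_corr`` is the
    correlation of repeated log-level draws within one patient.  Dropout is
    exponential; the default rate censors ~10% of patients by day 100.
    """

    n_patients: int = 1479
    seed: int = 0
    male_fraction: float = 0.57
    female_to_male_fraction: float = 0.22
    related_fraction: float = 0.40
    mrd_fraction: float = 0.30
    flutbi_fraction: float = 0.23
    age_median: float = 54.0
    age_sd: float = 13.0
    age_min: float = 17.0
    age_max: float = 76.0
    wbc_knots: tuple[tuple[float, float], ...] = (
        (0.0, 5.0),
        (8.0, 0.055),
        (20.0, 2.3),
        (30.0, 4.7),
        (41.0, 6.0),
        (70.0, 3.9),
    )
    wbc_patient_sigma: float = 0.35
    wbc_obs_sigma: float = 0.15
    csa_median: float = 178.0
    csa_p5: float = 48.0
    csa_p95: float = 333.1
    csa_cadence_days: float = 2.0
    csa_within_corr: float = 0.5
    dropout_rate: float = -float(np.log(0.9)) / 100.0
    train_fraction: float = 0.75

    def __post_init__(self) -> None:
        for name in (
            "male_fraction",
            "female_to_male_fraction",
            "related_fraction",
            "mrd_fraction",
            "flutbi_fraction",
            "train_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.mrd_fraction > self.related_fraction:
            raise ValueError("mrd_fraction cannot exceed related_fraction")
        if not self.csa_p5 < self.csa_median < self.csa_p95:
            raise ValueError("infeasible CsA marginals: need P5 < median < P95")
        days = [d for d, _ in self.wbc_knots]
        vals = [v for _, v in self.wbc_knots]
        if any(np.diff(days) <= 0) or any(v <= 0 for v in vals):
            raise ValueError("wbc_knots must have increasing days and positive values")
        nadir = days[int(np.argmin(vals))]
        peak = days[int(np.argmax(vals))]
        if nadir >= peak:
            raise ValueError("WBC nadir day must precede the peak day")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0.0 <= self.csa_within_corr <= 1.0:
            raise ValueError("csa_within_corr must lie in [0, 1]")


def _wbc_template(config: GeneratorConfig, days: np.ndarray) -> np.ndarray:
    """Log-linear interpolation through the knots, flat after the last."""
    kd = np.array([d for d, _ in config.wbc_knots])
    kv = np.log([v for _, v in config.wbc_knots])
    return np.exp(np.interp(days, kd, kv))


def _csa_from_normal(config: GeneratorConfig, z: np.ndarray) -> np.ndarray:
    """Two-piece lognormal transform matching median, P5 and P95 exactly."""
    mu = np.log(config.csa_median)
    sig_lo = (mu - np.log(config.csa_p5)) / _Z95
    sig_hi = (np.log(config.csa_p95) - mu) / _Z95
    return np.exp(mu + np.where(z < 0, sig_lo, sig_hi) * z)


def generate_cohort(
    config: GeneratorConfig,
    params: FinalModelParameters | None = None,
    split: bool = True,
) -> CohortDataset:
    """Generate a cohort whose event times follow the transit-delay model.

    Longitudinal series cover days 0-100 (WBC daily, CsA every
    ``csa_cadence_days``); the daily population median of the generated WBC
    counts becomes the cohort's reference table.  With ``split=True`` the
    static table carries a 3:1 train/test ``dataset`` label.
    """
    params = params or FinalModelParameters()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    ids = np.array([f"P{i:05d}" for i in range(n)])

    # --- static covariates ------------------------------------------------
    f2m = rng.random(n) < config.female_to_male_fraction
    related = rng.random(n) < config.related_fraction
    mrd = np.zeros(n, bool)
    if config.related_fraction > 0:
        mrd = related & (rng.random(n) < config.mrd_fraction / config.related_fraction)
    flu = rng.random(n) < config.flutbi_fraction
    if config.age_sd == 0:
        age = np.full(n, config.age_median)
    else:
        a, b = (
            (config.age_min - config.age_median) / config.age_sd,
            (config.age_max - config.age_median) / config.age_sd,
        )
        age = stats.truncnorm.rvs(
            a, b, loc=config.age_median, scale=config.age_sd, size=n, random_state=rng
        )

    # --- WBC: template x lognormal patient and observation noise ----------
    wbc_days = np.arange(0.0, HORIZON + 1.0)
    template = _wbc_template(config, wbc_days)
    pat_factor = np.exp(rng.normal(0.0, config.wbc_patient_sigma, size=(n, 1)))
    obs_factor = np.exp(rng.normal(0.0, config.wbc_obs_sigma, size=(n, wbc_days.size)))
    wbc_values = template[None, :] * pat_factor * obs_factor

    # --- CsA: correlated two-piece lognormal troughs ----------------------
    csa_days = np.arange(0.0, HORIZON + 1e-9, config.csa_cadence_days)
    rho = config.csa_within_corr
    z = np.sqrt(rho) * rng.standard_normal((n, 1)) + np.sqrt(1.0 - rho) * (
        rng.standard_normal((n, csa_days.size))
    )
    csa_values = _csa_from_normal(config, z)

    # --- population reference: daily median of the generated counts -------
    ref_median = np.median(wbc_values, axis=0)
    reference = pd.DataFrame({"day": wbc_days, "median_wbc": ref_median})

    # --- event times from the model itself --------------------------------
    times = model.day_grid()
    half = np.linspace(0.0, HORIZON, 2 * times.size - 1)
    csa_half = csa_values[:, np.clip(np.searchsorted(csa_days, half, "right") - 1, 0, None)]
    wbc_grid = wbc_values[:, np.clip(np.searchsorted(wbc_days, times, "right") - 1, 0, None)]
    med_grid = np.interp(times, wbc_days, ref_median)
    grids = PatientGrids(
        step=float(times[1] - times[0]),
        times=times,
        patient_ids=ids,
        age=age,
        related=related,
        mrd=mrd,
        f2m=f2m,
        flu=flu,
        event_time=np.full(n, HORIZON),
        event=np.zeros(n, int),
        csa_half=csa_half,
        wbc_ratio=np.maximum(wbc_grid, WBC_FLOOR) / med_grid,
    )
    _, H = grids.trajectories(params)
    t_event, is_event = _sample_from_cumhaz(times, H, rng.random(n))

    if config.dropout_rate > 0:
        dropout = rng.exponential(1.0 / config.dropout_rate, size=n)
    else:
        dropout = np.full(n, np.inf)
    censor = np.minimum(np.maximum(dropout, 0.5), HORIZON)
    event = (is_event == 1) & (t_event <= censor)
    obs_time = np.where(event, t_event, censor)

    static = pd.DataFrame(
        {
            "patient_id": ids,
            "age_years": age,
            "donor_related": related,
            "matched_related_donor": mrd,
            "female_to_male": f2m,
            "flutbi": flu,
            "event_time_days": obs_time,
            "event_indicator": event.astype(int),
        }
    )
    if split:
        perm = rng.permutation(n)
        n_train = int(round(config.train_fraction * n))
        label = np.empty(n, dtype=object)
        label[perm[:n_train]] = "train"
        label[perm[n_train:]] = "test"
        static["dataset"] = label

    longitudinal = pd.concat(
        [
            pd.DataFrame(
                {
                    "patient_id": np.repeat(ids, wbc_days.size),
                    "time_days": np.tile(wbc_days, n),
                    "analyte": "wbc",
                    "value": wbc_values.ravel(),
                }
            ),
            pd.DataFrame(
                {
                    "patient_id": np.repeat(ids, csa_days.size),
                    "time_days": np.tile(csa_days, n),
                    "analyte": "csa",
                    "value": csa_values.ravel(),
                }
            ),
        ],
        ignore_index=True,
    )
    cohort = CohortDataset(static=static, longitudinal=longitudinal, reference=reference)
    # the dense grids were already built to sample event times; cache them
    grids = dataclasses.replace(
        grids, event_time=obs_time, event=event.astype(int)
    )
    object.__setattr__(cohort, "_grids_cache", grids)
    return cohort


def population_reference(cohort: CohortDataset) -> PopulationReference:
    """Daily median of carried-forward WBC counts across patients."""
    wbc = cohort.longitudinal[cohort.longitudinal["analyte"] == "wbc"]
    if wbc.empty:
        raise ValueError("cohort has no WBC measurements")
    days = np.arange(0.0, HORIZON + 1.0)
    values = []
    for _, g in wbc.groupby("patient_id", sort=False):
        t = g["time_days"].to_numpy(float)
        v = g["value"].to_numpy(float)
        values.append(v[np.clip(np.searchsorted(t, days, "right") - 1, 0, None)])
    med = np.median(np.vstack(values), axis=0)
    if np.any(med <= 0):
        raise ValueError("daily median WBC is zero on some day")
    return PopulationReference(days, med)
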