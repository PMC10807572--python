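"""Cohort containers and CSV input/output.

On-disk layout (UTF-8, header row required):

* static CSV — one row per patient: ``patient_id, age_years, donor_related,
  matched_related_donor, female_to_male, flutbi, event_time_days,
  event_indicator`` (optional ``dataset`` column with train/test labels);
* longitudinal CSV — tidy long format: ``patient_id, time_days, analyte,
  value`` with ``analyte`` in {wbc, csa} (WBC in cells/nL, CsA in ng/mL);
* reference CSV — ``day, median_wbc``: the daily population median WBC.

``CohortDataset`` joins the three tables; ``PatientGrids`` is its dense
representation on a uniform day grid used by estimation, simulation and
risk stratification (covariates carried forward between measurements).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import model
from .model import (
    HORIZON,
    WBC_FLOOR,
    FinalModelParameters,
    LongitudinalCovariate,
    PopulationReference,
    StaticCovariates,
)

__all__ = [
    "CohortDataset",
    "PatientGrids",
    "read_static",
    "read_longitudinal",
    "read_reference",
]

STATIC_COLUMNS = [
    "patient_id",
    "age_years",
    "donor_related",
    "matched_related_donor",
    "female_to_male",
    "flutbi",
    "event_time_days",
    "event_indicator",
]
LONGITUDINAL_COLUMNS = ["patient_id", "time_days", "analyte", "value"]
REFERENCE_COLUMNS = ["day", "median_wbc"]

_FLAGS = ["donor_related", "matched_related_donor", "female_to_male", "flutbi"]


def _require_columns(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def read_static(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, STATIC_COLUMNS, path)
    df = df.copy()
    df["patient_id"] = df["patient_id"].astype(str)
    for c in _FLAGS:
        df[c] = df[c].astype(bool)
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise ValueError(f"{path}: duplicated patient_id {dup!r}")
    bad = ~((df["event_time_days"] > 0) & (df["event_time_days"] <= HORIZON))
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"{path}: row {row}: event_time_days must lie in (0, {HORIZON:g}]"
        )
    if (df["matched_related_donor"] & ~df["donor_related"]).any():
        raise ValueError(f"{path}: matched_related_donor implies donor_related")
    return df


def read_longitudinal(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, LONGITUDINAL_COLUMNS, path)
    df = df.copy()
    df["patient_id"] = df["patient_id"].astype(str)
    unknown = set(df["analyte"].unique()) - {"wbc", "csa"}
    if unknown:
        raise ValueError(f"{path}: unknown analyte values {sorted(unknown)}")
    if (df["value"] < 0).any():
        row = int(df.index[df["value"] < 0][0])
        raise ValueError(f"{path}: row {row}: negative measurement value")
    for (pid, analyte), g in df.groupby(["patient_id", "analyte"], sort=False):
        if np.any(np.diff(g["time_days"].to_numpy()) <= 0):
            raise ValueError(
                f"{path}: patient {pid} / {analyte}: time_days must be "
                "strictly increasing"
            )
    return df


def read_reference(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, REFERENCE_COLUMNS, path)
    if (df["median_wbc"] <= 0).any():
        raise ValueError(f"{path}: median_wbc must be positive")
    return df


@dataclass
class CohortDataset:
    """Static + longitudinal covariate tables and the WBC reference."""

    static: pd.DataFrame
    longitudinal: pd.DataFrame
    reference: pd.DataFrame

    def __post_init__(self) -> None:
        _require_columns(self.static, STATIC_COLUMNS, "static table")
        _require_columns(self.longitudinal, LONGITUDINAL_COLUMNS, "longitudinal table")
        _require_columns(self.reference, REFERENCE_COLUMNS, "reference table")

    @property
    def n_patients(self) -> int:
        return len(self.static)

    @property
    def patient_ids(self) -> list[str]:
        return self.static["patient_id"].astype(str).tolist()

    @classmethod
    def from_csv(cls, static_path, longitudinal_path, reference_path) -> "CohortDataset":
        return cls(
            read_static(static_path),
            read_longitudinal(longitudinal_path),
            read_reference(reference_path),
        )

    def to_csv(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "static": outdir / "static.csv",
            "longitudinal": outdir / "longitudinal.csv",
            "reference": outdir / "reference.csv",
        }
        self.static.to_csv(paths["static"], index=False)
        self.longitudinal.to_csv(paths["longitudinal"], index=False)
        self.reference.to_csv(paths["reference"], index=False)
        return paths

    def population_reference(self) -> PopulationReference:
        ref = self.reference.sort_values("day")
        return PopulationReference(
            ref["day"].to_numpy(float), ref["median_wbc"].to_numpy(float)
        )

    def patient(self, patient_id: str):
        """Return (StaticCovariates, wbc, csa) for one patient."""
        row = self.static.loc[self.static["patient_id"].astype(str) == str(patient_id)]
        if row.empty:
            raise KeyError(f"unknown patient_id {patient_id!r}")
        r = row.iloc[0]
        static = StaticCovariates(
            patient_id=str(r["patient_id"]),
            age_years=float(r["age_years"]),
            donor_related=bool(r["donor_related"]),
            matched_related_donor=bool(r["matched_related_donor"]),
            female_to_male=bool(r["female_to_male"]),
            flutbi=bool(r["flutbi"]),
            event_time_days=float(r["event_time_days"]),
            event_indicator=int(r["event_indicator"]),
        )
        series = {}
        for analyte in ("wbc", "csa"):
            g = self.longitudinal[
                (self.longitudinal["patient_id"].astype(str) == str(patient_id))
                & (self.longitudinal["analyte"] == analyte)
            ]
            if g.empty:
                raise ValueError(f"patient {patient_id}: no {analyte} measurements")
            series[analyte] = LongitudinalCovariate(
                str(patient_id), g["time_days"].to_numpy(float), g["value"].to_numpy(float)
            )
        return static, series["wbc"], series["csa"]

    def subset(self, patient_ids) -> "CohortDataset":
        ids = set(str(p) for p in patient_ids)
        return CohortDataset(
            self.static[self.static["patient_id"].astype(str).isin(ids)].reset_index(drop=True),
            self.longitudinal[
                self.longitudinal["patient_id"].astype(str).isin(ids)
            ].reset_index(drop=True),
            self.reference,
        )

    def to_grids(self, step: float = model.DEFAULT_STEP) -> "PatientGrids":
        cached = getattr(self, "_grids_cache", None)
        if cached is not None and cached.step == step:
            return cached
        return PatientGrids.from_dataset(self, step=step)


@dataclass
class PatientGrids:
    """Dense per-patient covariate arrays on a uniform day grid.

    ``csa_half`` is sampled on the half-step grid (2T-1 points) so RK4
    stages see the carried-forward CsA level at their exact time points;
    ``wbc_ratio`` is the floored WBC count over the daily population median
    at the T grid points.
    """

    step: float
    times: np.ndarray            # (T,)
    patient_ids: np.ndarray      # (n,)
    age: np.ndarray              # (n,)
    related: np.ndarray          # (n,) bool
    mrd: np.ndarray              # (n,) bool
    f2m: np.ndarray              # (n,) bool
    flu: np.ndarray              # (n,) bool
    event_time: np.ndarray       # (n,)
    event: np.ndarray            # (n,) int
    csa_half: np.ndarray         # (n, 2T-1)
    wbc_ratio: np.ndarray        # (n, T)

    @property
    def _log_wbc_ratio(self) -> np.ndarray:
        cached = getattr(self, "_log_wbc_ratio_cache", None)
        if cached is None:
            cached = np.log(self.wbc_ratio)
            object.__setattr__(self, "_log_wbc_ratio_cache", cached)
        return cached

    @classmethod
    def from_dataset(cls, dataset: CohortDataset, step: float = model.DEFAULT_STEP):
        times = model.day_grid(step)
        T = times.size
        half = np.linspace(0.0, times[-1], 2 * T - 1)
        st = dataset.static
        ids = st["patient_id"].astype(str).to_numpy()
        n = len(ids)
        ref = dataset.population_reference()
        med = ref.at(times)

        csa_half = np.empty((n, half.size))
        wbc_grid = np.empty((n, T))
        pos = {pid: i for i, pid in enumerate(ids)}
        seen = {"wbc": np.zeros(n, bool), "csa": np.zeros(n, bool)}
        for (pid, analyte), g in dataset.longitudinal.groupby(
            ["patient_id", "analyte"], sort=False
        ):
            i = pos.get(str(pid))
            if i is None:
                continue
            t = g["time_days"].to_numpy(float)
            v = g["value"].to_numpy(float)
            if not np.all(np.isfinite(v)):
                raise ValueError(f"patient {pid}: non-finite {analyte} value")
            if analyte == "csa":
                idx = np.clip(np.searchsorted(t, half, side="right") - 1, 0, None)
                csa_half[i] = v[idx]
            else:
                idx = np.clip(np.searchsorted(t, times, side="right") - 1, 0, None)
                wbc_grid[i] = v[idx]
            seen[analyte][i] = True
        for analyte, flags in seen.items():
            if not flags.all():
                pid = ids[int(np.flatnonzero(~flags)[0])]
                raise ValueError(f"patient {pid}: no {analyte} measurements")

        return cls(
            step=step,
            times=times,
            patient_ids=ids,
            age=st["age_years"].to_numpy(float),
            related=st["donor_related"].to_numpy(bool),
            mrd=st["matched_related_donor"].to_numpy(bool),
            f2m=st["female_to_male"].to_numpy(bool),
            flu=st["flutbi"].to_numpy(bool),
            event_time=st["event_time_days"].to_numpy(float),
            event=st["event_indicator"].to_numpy(int),
            csa_half=csa_half,
            wbc_ratio=np.maximum(wbc_grid, WBC_FLOOR) / med,
        )

    @property
    def n_patients(self) -> int:
        return self.patient_ids.size

    def static_multiplier(self, params: FinalModelParameters) -> np.ndarray:
        return (
            np.where(self.mrd, params.lam_mrd, 1.0)
            * np.where(self.f2m, params.lam_sex, 1.0)
            * np.where(self.flu, params.lam_flu, 1.0)
        )

    def trajectories(self, params: FinalModelParameters):
        """Vectorized h(t) and H(t), each of shape (n_patients, T)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # positivity floor handled silently here
            kel_half = model.kel_individual(
                self.csa_half, self.age[:, None], self.related[:, None], params
            )
        A = model.integrate_effect(self.times, kel_half, params.k_tr, params.n_transit)
        wbc_mult = (
            np.exp(params.gamma_wbc * self._log_wbc_ratio)
            if params.gamma_wbc != 0.0
            else 1.0
        )
        h = params.f * self.static_multiplier(params)[:, None] * wbc_mult * A
        H = model._cumulative_trapezoid(h, self.step)
        return h, H

    def at_event_times(self, values: np.ndarray) -> np.ndarray:
        """Linear interpolation of per-patient grid values at event times."""
        x = self.event_time / self.step
        i0 = np.minimum(x.astype(int), values.shape[1] - 2)
        w = x - i0
        rows = np.arange(values.shape[0])
        return values[rows, i0] * (1.0 - w) + values[rows, i0 + 1] * w
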