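"""Synthetic ICU cohort generator with a latent sepsis process.

Emulates the statistical structure of an ICU EHR extract in long format:
irregularly sampled vitals and laboratory values, antibiotic dose events,
microbiological culture draws, and stay-level metadata. Each septic stay
carries a latent infection time ``tau``; antibiotic and culture events are
placed at configurable offsets from ``tau`` and a monotone physiological
drift (tachycardia, hypotension, thrombocytopenia, rising bilirubin and
creatinine, falling GCS, oliguria, vasopressor onset) ramps in after a
configurable organ lag. Ground-truth timings are recorded per stay so that
onset labeling and risk modelling can be verified against a known answer.

All event and observation times are hours since ICU admission; every
generated time lies inside ``[0, los_hours)``. Output is a pure function of
the configuration (which includes the seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigError, ContractViolation

# name -> (baseline mean, between-patient sd, measurement noise sd,
#          mean observations per hour, physiological lower, upper bound)
# Baselines describe a stable (non-septic) adult ICU patient, sitting well
# inside the zero band of every SOFA threshold.
VARIABLE_TABLE: dict[str, tuple[float, float, float, float, float, float]] = {
    "heart_rate": (80.0, 8.0, 5.0, 0.7, 20.0, 220.0),
    "sbp": (120.0, 10.0, 7.0, 0.7, 40.0, 260.0),
    "dbp": (68.0, 7.0, 5.0, 0.7, 20.0, 160.0),
    "map": (86.0, 6.0, 5.0, 0.7, 30.0, 200.0),
    "resp_rate": (16.0, 2.0, 2.0, 0.7, 4.0, 60.0),
    "temp": (36.8, 0.25, 0.2, 0.5, 32.0, 42.0),
    "spo2": (97.0, 1.0, 1.0, 0.7, 60.0, 100.0),
    "fio2": (0.21, 0.0, 0.0, 0.25, 0.21, 1.0),
    "pao2": (95.0, 8.0, 7.0, 0.15, 30.0, 500.0),
    "pf_ratio": (455.0, 25.0, 18.0, 0.15, 40.0, 700.0),
    "gcs": (15.0, 0.0, 0.0, 0.25, 3.0, 15.0),
    "platelets": (250.0, 40.0, 15.0, 0.125, 1.0, 1000.0),
    "bilirubin": (0.7, 0.12, 0.08, 0.085, 0.05, 40.0),
    "creatinine": (0.9, 0.1, 0.06, 0.125, 0.1, 20.0),
    "bun": (15.0, 4.0, 2.0, 0.125, 1.0, 150.0),
    "lactate": (1.1, 0.25, 0.2, 0.125, 0.2, 25.0),
    "ph": (7.40, 0.02, 0.02, 0.17, 6.8, 7.8),
    "bicarbonate": (24.0, 1.5, 1.2, 0.125, 5.0, 50.0),
    "wbc": (8.0, 1.5, 1.0, 0.085, 0.5, 80.0),
    "hemoglobin": (11.5, 1.0, 0.4, 0.085, 3.0, 20.0),
    "glucose": (115.0, 15.0, 15.0, 0.17, 30.0, 800.0),
    "potassium": (4.0, 0.3, 0.2, 0.125, 1.5, 9.0),
    "sodium": (139.0, 2.0, 1.5, 0.125, 110.0, 175.0),
    "chloride": (103.0, 2.0, 1.5, 0.125, 70.0, 140.0),
    "magnesium": (2.0, 0.15, 0.1, 0.085, 0.5, 6.0),
    "calcium": (8.8, 0.4, 0.25, 0.085, 4.0, 15.0),
    "albumin": (3.4, 0.35, 0.2, 0.045, 1.0, 6.0),
    "alt": (28.0, 8.0, 4.0, 0.045, 2.0, 5000.0),
    "ast": (30.0, 8.0, 5.0, 0.045, 2.0, 5000.0),
    "urine_output": (70.0, 15.0, 15.0, 1.0, 0.0, 1000.0),
}

INTEGER_VARIABLES = {"gcs"}

# Full-effect deterioration deltas, reached after the linear ramp and held to
# discharge. Signs follow septic physiology. Platelet, creatinine, bilirubin
# and GCS shifts each cross at least one SOFA band on their own, so the total
# score rises by >= 2 by construction once the ramp completes.
DEFAULT_DRIFT: dict[str, float] = {
    "heart_rate": 45.0,
    "sbp": -25.0,
    "dbp": -12.0,
    "map": -20.0,
    "resp_rate": 14.0,
    "temp": 2.2,
    "spo2": -6.0,
    "pao2": -40.0,
    "pf_ratio": -240.0,
    "gcs": -4.0,
    "platelets": -160.0,
    "bilirubin": 2.3,
    "creatinine": 1.7,
    "bun": 25.0,
    "lactate": 4.5,
    "ph": -0.12,
    "bicarbonate": -7.0,
    "wbc": 12.0,
    "hemoglobin": -1.5,
    "glucose": 40.0,
    "chloride": 3.0,
    "albumin": -0.8,
    "urine_output": -55.0,
}

# systemic inflammatory-response variables deteriorate from the infection time
# itself; organ-dysfunction variables follow after the organ lag, so the SIRS
# phase precedes any SOFA-visible failure, as in clinical sepsis.
SIRS_VARIABLES = ("heart_rate", "resp_rate", "temp", "wbc", "lactate", "spo2")

ANTIBIOTICS = ("vancomycin", "piperacillin-tazobactam", "ceftriaxone", "meropenem")
CARE_UNITS = ("MICU", "SICU", "CCU", "CSRU")  # CSRU = cardiothoracic surgical
CARE_UNIT_PROBS = (0.50, 0.25, 0.15, 0.10)


@dataclass(frozen=True)
class CohortConfig:
    """Generator configuration; output tables are a pure function of it.

    Distribution parameters are (low, high) bounds of uniform draws unless
    noted. ``infection_time_frac`` places the latent infection time tau
    uniformly within that fraction band of the stay, keeping room for the
    antibiotic course and the deterioration ramp before discharge.
    """

    n_patients: int = 100
    septic_fraction: float = 0.3
    seed: int = 0
    los_range_hours: tuple[float, float] = (4.0, 480.0)
    los_lognorm_median: float = 60.0
    los_lognorm_sigma: float = 0.6
    infection_time_frac: tuple[float, float] = (0.15, 0.55)
    abx_offset_dist: tuple[float, float] = (8.0, 20.0)
    culture_offset_dist: tuple[float, float] = (6.0, 16.0)
    n_doses_dist: tuple[int, int] = (3, 6)
    dose_gap_dist: tuple[float, float] = (4.0, 12.0)
    organ_lag_dist: tuple[float, float] = (1.0, 4.0)
    drift_ramp_hours: float = 8.0
    drift_magnitudes: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DRIFT))
    sampling_rates: dict[str, float] = field(default_factory=dict)
    missingness: dict[str, float] = field(default_factory=dict)
    specimen_mix: float = 0.85
    background_abx_rate: float = 0.1
    background_culture_rate: float = 0.2
    vent_fraction_nonseptic: float = 0.15
    vent_fraction_septic: float = 0.5
    pressor_fraction_septic: float = 0.6
    pre_icu_abx_fraction: float = 0.08
    elective_surgical_fraction: float = 0.10

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError(f"n_patients must be >= 1, got {self.n_patients}")
        if not (0.0 <= self.septic_fraction <= 1.0):
            raise ConfigError(f"septic_fraction must be in [0, 1], got {self.septic_fraction}")
        lo, hi = self.los_range_hours
        if not (0 < lo < hi):
            raise ConfigError(f"los_range_hours must satisfy 0 < min < max, got {self.los_range_hours}")
        for name in ("background_abx_rate", "background_culture_rate", "drift_ramp_hours"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not (0.0 <= self.specimen_mix <= 1.0):
            raise ConfigError(f"specimen_mix must be in [0, 1], got {self.specimen_mix}")
        for fname in ("abx_offset_dist", "culture_offset_dist", "dose_gap_dist",
                      "organ_lag_dist", "infection_time_frac"):
            lo, hi = getattr(self, fname)
            if lo > hi:
                raise ConfigError(f"{fname} bounds out of order: {getattr(self, fname)}")
        if self.n_doses_dist[0] < 1 or self.n_doses_dist[0] > self.n_doses_dist[1]:
            raise ConfigError(f"n_doses_dist must satisfy 1 <= min <= max, got {self.n_doses_dist}")
        for dname, d in (("sampling_rates", self.sampling_rates), ("missingness", self.missingness)):
            for var, v in d.items():
                if v < 0 or (dname == "missingness" and v > 1):
                    raise ConfigError(f"{dname}[{var}] out of range: {v}")

    def rate_for(self, variable: str) -> float:
        if variable in self.sampling_rates:
            return self.sampling_rates[variable]
        return VARIABLE_TABLE[variable][3]


@dataclass
class CohortTables:
    """The five generated tables plus the config manifest."""

    stays: pd.DataFrame
    observations: pd.DataFrame
    doses: pd.DataFrame
    cultures: pd.DataFrame
    ground_truth: pd.DataFrame
    config: Optional[CohortConfig] = None

    def save(self, directory: str | Path, fmt: str = "csv") -> None:
        """Write the five tables (csv or parquet) and a JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        tables = {
            "stays": self.stays,
            "observations": self.observations,
            "doses": self.doses,
            "cultures": self.cultures,
            "ground_truth": self.ground_truth,
        }
        for name, df in tables.items():
            if fmt == "csv":
                df.to_csv(directory / f"{name}.csv", index=False)
            elif fmt == "parquet":
                df.to_parquet(directory / f"{name}.parquet", index=False)
            else:
                raise ConfigError(f"fmt must be 'csv' or 'parquet', got {fmt!r}")
        if self.config is not None:
            manifest = {"config": _jsonable(asdict(self.config)), "tables": sorted(tables)}
            (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | Path, fmt: str = "csv") -> "CohortTables":
        directory = Path(directory)
        read = pd.read_csv if fmt == "csv" else pd.read_parquet
        return cls(
            stays=read(directory / f"stays.{fmt}"),
            observations=read(directory / f"observations.{fmt}"),
            doses=read(directory / f"doses.{fmt}"),
            cultures=read(directory / f"cultures.{fmt}"),
            ground_truth=read(directory / f"ground_truth.{fmt}"),
        )

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for df in (self.stays, self.observations, self.doses, self.cultures, self.ground_truth):
            h.update(df.to_csv(index=False).encode())
        return h.hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def drift_delta(times: np.ndarray, tau: float, lag: float, ramp_hours: float,
                magnitude: float) -> np.ndarray:
    """Deterministic deterioration delta at the given observation times.

    Zero before ``tau + lag``, then a linear ramp over ``ramp_hours`` to the
    full ``magnitude``, held thereafter. Pure function of its arguments, so
    two stays with identical times/parameters receive identical deltas.
    """
    t = np.asarray(times, dtype=float)
    if ramp_hours <= 0:
        return np.where(t >= tau + lag, magnitude, 0.0)
    frac = np.clip((t - (tau + lag)) / ramp_hours, 0.0, 1.0)
    return magnitude * frac


def inject_sepsis_trajectory(observations: pd.DataFrame, tau: float, lag: float,
                             config: CohortConfig, los_hours: float) -> pd.DataFrame:
    """Apply the configured deterioration drift to one stay's observations.

    Returns a copy with post-``tau + lag`` values shifted by the ramped drift
    magnitudes and clipped to physiological bounds. Values before ``tau`` are
    untouched, so the pre-infection distribution equals the non-septic one.
    """
    if not (0.0 <= tau <= los_hours):
        raise ContractViolation(f"tau={tau} outside stay [0, {los_hours}]")
    out = observations.copy()
    for var, mag in config.drift_magnitudes.items():
        if var not in VARIABLE_TABLE:
            raise ConfigError(f"drift_magnitudes names unknown variable {var!r}")
        mask = out["variable"].to_numpy() == var
        if not mask.any():
            continue
        var_lag = 0.0 if var in SIRS_VARIABLES else lag
        times = out.loc[mask, "time"].to_numpy(dtype=float)
        vals = out.loc[mask, "value"].to_numpy(dtype=float)
        vals = vals + drift_delta(times, tau, var_lag, config.drift_ramp_hours, mag)
        lo, hi = VARIABLE_TABLE[var][4], VARIABLE_TABLE[var][5]
        vals = np.clip(vals, lo, hi)
        if var in INTEGER_VARIABLES:
            vals = np.round(vals)
        out.loc[mask, "value"] = vals
    return out


def _sample_stay_observations(rng: np.random.Generator, stay_id: int, los: float,
                              config: CohortConfig) -> pd.DataFrame:
    frames = []
    for var, (mean, bsd, nsd, _rate, lo, hi) in VARIABLE_TABLE.items():
        rate = config.rate_for(var)
        n = rng.poisson(rate * los)
        if n == 0:
            continue
        times = np.sort(rng.uniform(0.0, los, size=n))
        baseline = mean + bsd * rng.standard_normal()
        vals = baseline + nsd * rng.standard_normal(n)
        vals = np.clip(vals, lo, hi)
        if var in INTEGER_VARIABLES:
            vals = np.round(vals)
        miss = config.missingness.get(var, 0.0)
        if miss > 0:
            keep = rng.uniform(size=n) >= miss
            times, vals = times[keep], vals[keep]
        if len(times) == 0:
            continue
        frames.append(pd.DataFrame({
            "stay_id": stay_id, "variable": var, "time": times, "value": vals,
        }))
    if not frames:
        return pd.DataFrame(columns=["stay_id", "variable", "time", "value"])
    return pd.concat(frames, ignore_index=True)


def generate_cohort(config: CohortConfig) -> CohortTables:
    """Generate a full synthetic cohort.

    Returns stays, long-format observations, antibiotic dose events, culture
    events, and the ground-truth table (latent timings + a
    ``rule_conforming`` flag marking septic stays whose infection events were
    placed so as to satisfy the suspicion pairing rules).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    stays_rows, obs_frames, dose_rows, cult_rows, truth_rows = [], [], [], [], []
    lo_los, hi_los = config.los_range_hours
    n_septic = int(round(config.n_patients * config.septic_fraction))
    septic_flags = np.zeros(config.n_patients, dtype=bool)
    septic_flags[:n_septic] = True
    rng.shuffle(septic_flags)

    for i in range(config.n_patients):
        stay_id = i + 1
        patient_id = 10_000 + i
        mu = np.log(config.los_lognorm_median)
        los = float(np.clip(rng.lognormal(mu, config.los_lognorm_sigma), lo_los, hi_los))
        is_septic = bool(septic_flags[i])

        age = float(np.clip(rng.normal(65, 15), 18, 95))
        sex = "F" if rng.uniform() < 0.45 else "M"
        care_unit = CARE_UNITS[rng.choice(len(CARE_UNITS), p=CARE_UNIT_PROBS)]
        elective = bool(rng.uniform() < config.elective_surgical_fraction)
        pre_icu_abx = bool(rng.uniform() < config.pre_icu_abx_fraction)
        hosp_to_icu = float(rng.uniform(0, 48))

        obs = _sample_stay_observations(rng, stay_id, los, config)

        # ventilation: background from admission, or sepsis-driven after the lag
        vent_base = rng.uniform() < config.vent_fraction_nonseptic
        vent_times, vent_vals = [0.0], [1.0 if vent_base else 0.0]
        ever_vent = vent_base

        tau = lag = t_abx0 = t_cult = np.nan
        rule_conforming = False
        if is_septic:
            f_lo, f_hi = config.infection_time_frac
            tau = float(rng.uniform(f_lo, f_hi) * los)
            lag = float(rng.uniform(*config.organ_lag_dist))
            obs = inject_sepsis_trajectory(obs, tau, lag, config, los)

            # antibiotic course tied to the infection
            t_abx0 = tau + float(rng.uniform(*config.abx_offset_dist))
            n_doses = int(rng.integers(config.n_doses_dist[0], config.n_doses_dist[1] + 1))
            gaps = rng.uniform(*config.dose_gap_dist, size=max(n_doses - 1, 0))
            dose_times = t_abx0 + np.concatenate([[0.0], np.cumsum(gaps)])
            dose_times = dose_times[dose_times < los]
            drug = ANTIBIOTICS[rng.choice(len(ANTIBIOTICS))]
            for t in dose_times:
                dose_rows.append((stay_id, drug, float(t)))

            t_cult = tau + float(rng.uniform(*config.culture_offset_dist))
            specimen = "blood" if rng.uniform() < config.specimen_mix else "other"
            culture_in_stay = 0.0 <= t_cult < los
            if culture_in_stay:
                cult_rows.append((stay_id, specimen, float(t_cult)))

            if len(dose_times) == 0 or t_abx0 >= los:
                t_abx0 = np.nan
                rule_conforming = False
            else:
                n_in_96 = int(np.sum(dose_times <= dose_times[0] + 96.0))
                if culture_in_stay and specimen == "blood" and n_in_96 >= 2:
                    if t_abx0 <= t_cult:
                        rule_conforming = (t_cult - t_abx0) <= 24.0
                    else:
                        rule_conforming = (t_abx0 - t_cult) <= 72.0
                else:
                    rule_conforming = False
            if not culture_in_stay:
                t_cult = np.nan

            if rng.uniform() < config.vent_fraction_septic and not vent_base:
                t_vent = tau + lag + float(rng.uniform(0, 6))
                if t_vent < los:
                    vent_times.append(t_vent)
                    vent_vals.append(1.0)
                    ever_vent = True
            if rng.uniform() < config.pressor_fraction_septic:
                t_press = tau + lag + float(rng.uniform(2, 8))
                hours_on = np.arange(t_press, los, 1.0)
                if len(hours_on):
                    dose_ramp = np.clip(0.05 + 0.01 * np.arange(len(hours_on)), 0.05, 0.15)
                    press = pd.DataFrame({
                        "stay_id": stay_id,
                        "variable": "norepinephrine_dose",
                        "time": hours_on,
                        "value": dose_ramp,
                    })
                    obs = pd.concat([obs, press], ignore_index=True)

        # background (infection-decoupled) antibiotic and culture events
        bg_times = []
        for _ in range(rng.poisson(config.background_abx_rate)):
            t_bg = float(rng.uniform(0, los))
            bg_times.append(t_bg)
            dose_rows.append((
                stay_id,
                ANTIBIOTICS[rng.choice(len(ANTIBIOTICS))],
                t_bg,
            ))
        for _ in range(rng.poisson(config.background_culture_rate)):
            specimen = "blood" if rng.uniform() < config.specimen_mix else "other"
            t_bg = float(rng.uniform(0, los))
            bg_times.append(t_bg)
            cult_rows.append((stay_id, specimen, t_bg))
        # a background event preceding the infection pair can form an earlier
        # suspicion episode of its own, so such stays are not "constructed to
        # satisfy the pairing rules" for the infection events (conservative)
        if rule_conforming and bg_times:
            infection_suspicion = min(t_abx0, t_cult)
            if min(bg_times) < infection_suspicion:
                rule_conforming = False

        vent = pd.DataFrame({
            "stay_id": stay_id, "variable": "vent_flag",
            "time": vent_times, "value": vent_vals,
        })
        obs = pd.concat([obs, vent], ignore_index=True)
        obs = obs.sort_values(["variable", "time"], kind="mergesort").reset_index(drop=True)
        obs_frames.append(obs)

        stays_rows.append({
            "stay_id": stay_id,
            "patient_id": patient_id,
            "los_hours": los,
            "age": age,
            "sex": sex,
            "care_unit": care_unit,
            "elective_surgical": elective,
            "pre_icu_antibiotics": pre_icu_abx,
            "ever_ventilated": ever_vent,
            "hosp_to_icu_hours": hosp_to_icu,
            "source_system": "metavision",
        })
        truth_rows.append({
            "stay_id": stay_id,
            "is_septic": is_septic,
            "tau_infection": tau,
            "true_first_abx": t_abx0,
            "true_first_culture": t_cult,
            "true_organ_deterioration_time": tau + lag if is_septic else np.nan,
            "rule_conforming": rule_conforming,
        })

    stays = pd.DataFrame(stays_rows)
    observations = (
        pd.concat(obs_frames, ignore_index=True)
        if obs_frames else pd.DataFrame(columns=["stay_id", "variable", "time", "value"])
    )
    doses = pd.DataFrame(dose_rows, columns=["stay_id", "drug", "time"])
    cultures = pd.DataFrame(cult_rows, columns=["stay_id", "specimen", "time"])
    ground_truth = pd.DataFrame(truth_rows)
    return CohortTables(stays, observations, doses, cultures, ground_truth, config=config)
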