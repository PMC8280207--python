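"""Reproducible synthetic NICU cohorts with ground-truth deterioration onsets.

The generator emulates the statistical structure the monitor assumes: per
infant, 1-Hz recordings of heart rate (HR, bpm), respiratory rate (RR,
breaths/min), oxygen saturation (SPO2, %), and one of invasive (ART-M) or
non-invasive (NIBP-M) mean blood pressure (mmHg); a clinical table (sex,
race, gestational age, birth weight, outcome, prior length of stay,
CRIB-II score); missing samples; artifact spikes; and, for dying infants,
a linear deterioration ramp with inflated noise whose onset time is the
ground-truth turning point.  Everything is a pure function of the spec and
its seed.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SignalModel",
    "Deterioration",
    "SyntheticSpec",
    "RawRecording",
    "ClinicalRecord",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "SIGNALS",
]

SIGNALS = ("HR", "RR", "SPO2", "ART-M", "NIBP-M")
RACES = ("Asian", "Black", "Hispanic", "White", "Other")

#: Mean gestational age (weeks) the baselines are anchored at.
GA_REFERENCE_WEEKS = 26.7


@dataclass
class SignalModel:
    """Baseline mean/SD of one vital sign plus its deterioration behaviour."""

    mean: float
    sd: float
    drift: float          # signed total drift (units) reached at death
    ga_slope: float = 0.0  # baseline change per week of gestational age


@dataclass
class Deterioration:
    """Pre-mortem deterioration: a linear ramp from onset to death.

    Onset precedes death by ``onset_hours``; each signal drifts linearly by
    its configured magnitude and its noise SD is multiplied by
    ``noise_inflation`` from onset onward.
    """

    onset_hours: float = 6.0
    noise_inflation: float = 2.0


def _default_signals() -> dict[str, SignalModel]:
    # Plausible VLBW preterm values: tachycardic baseline HR, MAP close to
    # gestational age in weeks, deterioration = bradycardia + desaturation +
    # hypotension with increased respiratory instability.
    return {
        "HR": SignalModel(mean=155.0, sd=10.0, drift=-25.0),
        "RR": SignalModel(mean=50.0, sd=8.0, drift=+15.0),
        "SPO2": SignalModel(mean=93.0, sd=3.0, drift=-12.0),
        "ART-M": SignalModel(mean=27.0, sd=5.0, drift=-10.0, ga_slope=1.0),
        "NIBP-M": SignalModel(mean=27.0, sd=5.0, drift=-10.0, ga_slope=1.0),
    }


@dataclass
class SyntheticSpec:
    """Full parameterization of a synthetic cohort."""

    n_infants: int = 40
    death_fraction: float = 0.5
    recording_hours: float = 80.0
    signals: dict[str, SignalModel] = field(default_factory=_default_signals)
    deterioration: Deterioration = field(default_factory=Deterioration)
    missing_rate: float = 0.05
    artifact_rate: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        for name, value in (("death_fraction", self.death_fraction),
                            ("missing_rate", self.missing_rate),
                            ("artifact_rate", self.artifact_rate)):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be a proportion in [0, 1]: {value}")
        if self.recording_hours < 6.0:
            raise ValueError(
                f"recording_hours must be >= 6 (shorter recordings are "
                f"excluded): {self.recording_hours}")
        if self.n_infants < 1:
            raise ValueError(f"n_infants must be >= 1: {self.n_infants}")
        if self.deterioration.onset_hours <= 0:
            raise ValueError(
                f"deterioration.onset_hours must be > 0: "
                f"{self.deterioration.onset_hours}")
        missing = set(SIGNALS) - set(self.signals)
        if missing:
            raise ValueError(f"signals missing models for {sorted(missing)}")


@dataclass
class RawRecording:
    """One infant's 1-Hz multichannel recording.

    Timestamps are elapsed seconds from recording start.  Exactly one of the
    two blood-pressure channels is present; the other is all-NaN.
    """

    infant_id: str
    start_time: float
    series: dict[str, np.ndarray]   # each (n_samples,), NaN = missing
    bp_channel: str                 # "ART-M" or "NIBP-M"

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.series.values())))


@dataclass
class ClinicalRecord:
    infant_id: str
    sex: str
    race: str
    ga_weeks: float
    birth_weight_g: float
    died: bool
    death_time: float | None        # elapsed seconds; present iff died
    prior_stay_hours: float
    crib2_score: int | None
    true_turning_onset: float | None = None  # synthetic ground truth (dying only)

    def __post_init__(self) -> None:
        if self.died != (self.death_time is not None):
            raise ValueError("death_time must be present iff died")
        if self.true_turning_onset is not None and not self.died:
            raise ValueError("true_turning_onset only applies to dying infants")


def _valid_upper(name: str) -> float:
    return {"HR": 250.0, "RR": 120.0, "SPO2": 100.0, "ART-M": 90.0, "NIBP-M": 90.0}[name]


def _clean_range(name: str) -> tuple[float, float]:
    """Interval clean (non-artifact) samples are clipped into; strictly inside
    the monitor's valid ranges (NIBP-M's lower endpoint is open, so its floor
    sits just above 10)."""
    return {"HR": (0.5, 250.0), "RR": (0.5, 120.0), "SPO2": (0.5, 100.0),
            "ART-M": (10.0, 90.0), "NIBP-M": (10.5, 90.0)}[name]


def generate_cohort(spec: SyntheticSpec) -> tuple[list[RawRecording], list[ClinicalRecord]]:
    """Generate recordings and clinical records; deterministic in spec.seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_infants
    n_dead = int(round(n * spec.death_fraction))
    died_flags = np.zeros(n, dtype=bool)
    died_flags[rng.choice(n, size=n_dead, replace=False)] = True

    n_samples = int(round(spec.recording_hours * 3600))
    onset_s = spec.deterioration.onset_hours * 3600.0

    recordings: list[RawRecording] = []
    clinical: list[ClinicalRecord] = []
    for i in range(n):
        infant_id = f"inf{i:04d}"
        died = bool(died_flags[i])
        ga = float(np.clip(rng.normal(GA_REFERENCE_WEEKS, 2.3) - (1.5 if died else 0.0),
                           22.0, 32.0))
        bw = float(np.clip(rng.normal(170.0 * (ga - GA_REFERENCE_WEEKS) + 929.0, 120.0),
                           350.0, 1500.0))
        sex = "male" if rng.random() < 0.51 else "female"
        race = RACES[rng.choice(len(RACES), p=[0.05, 0.35, 0.1, 0.45, 0.05])]
        prior_stay = float(rng.exponential(240.0))
        crib2 = int(np.clip(round(rng.normal(10.0 + (3.5 if died else -1.0)
                                             - 0.8 * (ga - GA_REFERENCE_WEEKS), 2.0)),
                            2, 18))
        bp_channel = "ART-M" if rng.random() < 0.5 else "NIBP-M"
        death_time = float(n_samples) if died else None
        onset = death_time - onset_s if died else None

        t = np.arange(n_samples, dtype=float)
        series: dict[str, np.ndarray] = {}
        for name in SIGNALS:
            if name in ("ART-M", "NIBP-M") and name != bp_channel:
                series[name] = np.full(n_samples, np.nan)
                continue
            sm = spec.signals[name]
            baseline = sm.mean + sm.ga_slope * (ga - GA_REFERENCE_WEEKS) \
                + rng.normal(0.0, sm.sd / 4.0)
            noise_sd = np.full(n_samples, sm.sd)
            drift = np.zeros(n_samples)
            if died:
                ramp = np.clip((t - onset) / onset_s, 0.0, 1.0)
                drift = sm.drift * ramp
                noise_sd = np.where(t >= onset,
                                    sm.sd * spec.deterioration.noise_inflation,
                                    sm.sd)
            x = baseline + drift + rng.normal(0.0, 1.0, n_samples) * noise_sd
            # keep clean samples physiologic (inside the valid range)
            lo, hi = _clean_range(name)
            x = np.clip(x, lo, hi)
            if spec.artifact_rate > 0:
                hit = rng.random(n_samples) < spec.artifact_rate
                # out-of-valid-range spikes: dropouts to 0 or implausible highs
                spikes = np.where(rng.random(n_samples) < 0.5, 0.0,
                                  _valid_upper(name) * 1.5 + 10.0)
                x = np.where(hit, spikes, x)
            if spec.missing_rate > 0:
                x = np.where(rng.random(n_samples) < spec.missing_rate, np.nan, x)
            series[name] = x

        recordings.append(RawRecording(infant_id=infant_id, start_time=0.0,
                                       series=series, bp_channel=bp_channel))
        clinical.append(ClinicalRecord(
            infant_id=infant_id, sex=sex, race=race, ga_weeks=ga,
            birth_weight_g=bw, died=died, death_time=death_time,
            prior_stay_hours=prior_stay, crib2_score=crib2,
            true_turning_onset=onset))
    return recordings, clinical


# -- on-disk format -----------------------------------------------------

CLINICAL_COLUMNS = ["infant_id", "sex", "race", "ga_weeks", "birth_weight_g",
                    "died", "death_time", "prior_stay_hours", "crib2_score",
                    "true_turning_onset"]


def write_cohort(recordings: list[RawRecording], clinical: list[ClinicalRecord],
                 out_dir: str | Path) -> dict:
    """Write one CSV per infant, a clinical table, and a JSON manifest."""
    ids_r = {r.infant_id for r in recordings}
    ids_c = {c.infant_id for c in clinical}
    if ids_r != ids_c:
        raise ValueError(f"inconsistent infant ids: {sorted(ids_r ^ ids_c)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for rec in recordings:
        fname = f"{rec.infant_id}.csv"
        df = pd.DataFrame({"timestamp": np.arange(rec.n_samples, dtype=int)})
        for name in SIGNALS:
            df[name] = rec.series[name]
        df.to_csv(out_dir / fname, index=False, na_rep="")
        files.append(fname)
    with open(out_dir / "clinical.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(CLINICAL_COLUMNS)
        for c in clinical:
            w.writerow([c.infant_id, c.sex, c.race, f"{c.ga_weeks:.6g}",
                        f"{c.birth_weight_g:.6g}", int(c.died),
                        "" if c.death_time is None else f"{c.death_time:.6g}",
                        f"{c.prior_stay_hours:.6g}",
                        "" if c.crib2_score is None else c.crib2_score,
                        "" if c.true_turning_onset is None
                        else f"{c.true_turning_onset:.6g}"])
    manifest = {"n_infants": len(recordings), "series_files": files,
                "clinical_file": "clinical.csv"}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def read_cohort(in_dir: str | Path) -> tuple[list[RawRecording], list[ClinicalRecord]]:
    """Read a cohort written by :func:`write_cohort`."""
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    recordings = []
    for fname in manifest["series_files"]:
        df = pd.read_csv(in_dir / fname)
        series = {name: df[name].to_numpy(dtype=float) for name in SIGNALS}
        art_present = np.isfinite(series["ART-M"]).any()
        recordings.append(RawRecording(
            infant_id=Path(fname).stem, start_time=0.0, series=series,
            bp_channel="ART-M" if art_present else "NIBP-M"))
    cdf = pd.read_csv(in_dir / "clinical.csv")
    clinical = []
    for _, row in cdf.iterrows():
        died = bool(row["died"])
        clinical.append(ClinicalRecord(
            infant_id=row["infant_id"], sex=row["sex"], race=row["race"],
            ga_weeks=float(row["ga_weeks"]),
            birth_weight_g=float(row["birth_weight_g"]), died=died,
            death_time=float(row["death_time"]) if died else None,
            prior_stay_hours=float(row["prior_stay_hours"]),
            crib2_score=None if pd.isna(row["crib2_score"])
            else int(row["crib2_score"]),
            true_turning_onset=None if pd.isna(row.get("true_turning_onset"))
            else float(row["true_turning_onset"])))
    return recordings, clinical
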