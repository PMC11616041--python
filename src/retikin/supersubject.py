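"""Composite ("super-subject") dataset construction.

Converts per-subject plasma tracer measurements into fraction-of-dose
values (FDp), screens out subjects with implausible results, and pools
the remainder into per-time geometric means with the fractional
standard deviation (FSD) weights used for model fitting.

Each participant contributes only 1-3 timed samples; treating the
per-time geometric means as one composite subject lets a single
compartmental model be fitted to the whole group.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "ALLOWED_TIMES",
    "AUXILIARY_TIMES",
    "NADLER_FEMALE_COEFFS",
    "DEFAULT_DOSE_UMOL",
    "SubjectRecord",
    "CompositeDataset",
    "estimate_plasma_volume",
    "compute_fdp",
    "compute_plasma_mass",
    "assign_fsd_weights",
    "build_composite",
    "group_plasma_mass",
    "read_subject_records",
]

#: study sampling times in days (6, 9, 12 h map to 0.25, 0.375, 0.5 d)
ALLOWED_TIMES: tuple[float, ...] = (
    0.25, 0.375, 0.5, 1.0, 2.0, 4.0, 7.0, 11.0, 14.0, 21.0, 28.0,
    35.0, 49.0, 63.0, 77.0, 91.0,
)
#: the 13 auxiliary times (everything except the core days 14, 21, 28)
AUXILIARY_TIMES: tuple[float, ...] = tuple(
    t for t in ALLOWED_TIMES if t not in (14.0, 21.0, 28.0)
)

#: Nadler total-blood-volume regression for women: litres from height (m)
#: and weight (kg).  Recorded here so the coefficients are auditable and
#: overridable.
NADLER_FEMALE_COEFFS: tuple[float, float, float] = (0.3561, 0.03308, 0.1833)

DEFAULT_DOSE_UMOL = 6.84


def estimate_plasma_volume(
    height_m: float,
    weight_kg: float,
    hematocrit: float,
    *,
    coeffs: tuple[float, float, float] = NADLER_FEMALE_COEFFS,
) -> float:
    """Plasma volume (L) from the Nadler blood-volume regression.

    Total blood volume = c0*H^3 + c1*W + c2 (litres); plasma volume is
    the non-cellular fraction, blood volume x (1 - hematocrit).
    """
    if not (0.0 < hematocrit < 1.0):
        raise ValidationError(f"hematocrit {hematocrit!r} outside (0, 1)")
    if not (height_m > 0 and weight_kg > 0):
        raise ValidationError("height and weight must be positive")
    c0, c1, c2 = coeffs
    blood_volume = c0 * height_m**3 + c1 * weight_kg + c2
    return blood_volume * (1.0 - hematocrit)


def compute_fdp(dh6_conc: float, plasma_volume: float, dose: float) -> float:
    """Fraction of the tracer dose in plasma.

    FDp = labeled-retinol concentration (µmol/L) x plasma volume (L)
    / dose (µmol).
    """
    if dose <= 0:
        raise ValidationError("dose must be > 0")
    if plasma_volume <= 0:
        raise ValidationError("plasma volume must be > 0")
    if dh6_conc < 0:
        raise ValidationError("tracer concentration must be >= 0")
    return dh6_conc * plasma_volume / dose


def compute_plasma_mass(total_retinol: float, plasma_volume: float) -> float:
    """Plasma retinol pool (µmol): concentration (µmol/L) x volume (L)."""
    if total_retinol <= 0 or plasma_volume <= 0:
        raise ValidationError("concentration and volume must be > 0")
    return total_retinol * plasma_volume


@dataclass
class SubjectRecord:
    """One participant: anthropometry, dose, and timed samples.

    ``samples`` holds (time_d, dh6_retinol µmol/L, total_retinol µmol/L)
    tuples; ``hematocrit`` may be None (imputed from the cohort mean when
    plasma volume is needed).
    """

    subject_id: str
    weight: float
    height: float
    hematocrit: float | None = None
    dose: float = DEFAULT_DOSE_UMOL
    samples: list[tuple[float, float, float]] = field(default_factory=list)
    hematocrit_imputed: bool = field(default=False, compare=False)

    def plasma_volume(self, fallback_hematocrit: float | None = None) -> float:
        hct = self.hematocrit
        if hct is None or (isinstance(hct, float) and math.isnan(hct)):
            if fallback_hematocrit is None:
                raise ValidationError(
                    f"subject {self.subject_id}: hematocrit missing and no fallback given"
                )
            hct = fallback_hematocrit
            self.hematocrit_imputed = True
        return estimate_plasma_volume(self.height, self.weight, hct)


@dataclass(frozen=True)
class CompositeDataset:
    """Per-time geometric-mean FDp with fitting weights."""

    times: np.ndarray          # days post-dose
    gm_fdp: np.ndarray         # geometric mean fraction of dose in plasma
    n: np.ndarray              # subjects contributing at each time
    fsd_weight: np.ndarray     # fractional standard deviation for fitting

    def __post_init__(self):
        if not (self.gm_fdp > 0).all():
            raise ValidationError("gm_fdp must be > 0 at every retained time")
        if not (self.n >= 1).all():
            raise ValidationError("each retained time needs n >= 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_d": self.times, "n": self.n, "gm_fdp": self.gm_fdp,
             "fsd_weight": self.fsd_weight}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CompositeDataset":
        df = df.sort_values("time_d")
        return cls(
            times=df["time_d"].to_numpy(float),
            gm_fdp=df["gm_fdp"].to_numpy(float),
            n=df["n"].to_numpy(int),
            fsd_weight=df["fsd_weight"].to_numpy(float),
        )


#: default FSD weighting: tight on the day everyone was sampled, looser
#: on the half-cohort days, loosest where n <= 4
DEFAULT_FSD_SCHEME = {"day14": 0.02, "day21_28": 0.05, "sparse": 0.5, "other": 0.1}


def assign_fsd_weights(
    time_d: float,
    n_at_time: int,
    scheme: Mapping[str, float] | None = None,
) -> float:
    """Fractional standard deviation assigned to one composite point.

    Day 14 (full cohort) gets 0.02; days 21 and 28 (half cohort each)
    0.05; any time with n <= 4 gets 0.5; all other times 0.1.
    """
    if n_at_time < 1:
        raise ValidationError("n_at_time must be >= 1")
    s = dict(DEFAULT_FSD_SCHEME)
    if scheme:
        s.update(scheme)
    if time_d == 14.0:
        return s["day14"]
    if time_d in (21.0, 28.0):
        return s["day21_28"]
    if n_at_time <= 4:
        return s["sparse"]
    return s["other"]


def _geometric_mean(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0):
        raise ValidationError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(values))))


def _subject_fdp_table(
    records: Sequence[SubjectRecord],
    fallback_hematocrit: float | None,
) -> pd.DataFrame:
    """Long table (subject_id, time_d, fdp) using each subject's own
    plasma-volume estimate; missing hematocrits use the cohort mean."""
    if fallback_hematocrit is None:
        known = [r.hematocrit for r in records
                 if r.hematocrit is not None and not math.isnan(r.hematocrit)]
        fallback_hematocrit = float(np.mean(known)) if known else None
    rows = []
    for rec in records:
        pv = rec.plasma_volume(fallback_hematocrit)
        for time_d, dh6, _total in rec.samples:
            rows.append((rec.subject_id, float(time_d), compute_fdp(dh6, pv, rec.dose)))
    return pd.DataFrame(rows, columns=["subject_id", "time_d", "fdp"])


def build_composite(
    records: Sequence[SubjectRecord],
    *,
    exclusion_threshold: float = 0.1,
    fsd_scheme: Mapping[str, float] | None = None,
    fallback_hematocrit: float | None = None,
) -> tuple[CompositeDataset, list[str]]:
    """Pool per-subject FDp values into the composite dataset.

    A subject is excluded whole (all samples) when *every* one of their
    FDp values falls below ``exclusion_threshold`` times the
    contemporaneous cohort geometric mean — the implausibly-low screen
    for incompletely ingested doses.  Returns the composite dataset and
    the list of excluded subject ids.
    """
    if not records:
        raise ValidationError("no subject records supplied")
    for rec in records:
        if not rec.samples:
            raise ValidationError(f"subject {rec.subject_id} has no samples")

    table = _subject_fdp_table(records, fallback_hematocrit)
    if np.any(table["fdp"] <= 0):
        bad = table.loc[table["fdp"] <= 0, "subject_id"].unique().tolist()
        raise ValidationError(f"non-positive FDp for subjects {bad}; cannot take logs")

    # implausibility screen against per-time cohort geometric means
    gm_by_time = table.groupby("time_d")["fdp"].apply(_geometric_mean)
    rel = table["fdp"].to_numpy() / gm_by_time.loc[table["time_d"]].to_numpy()
    table = table.assign(rel=rel)
    excluded = [
        sid for sid, grp in table.groupby("subject_id")
        if (grp["rel"] < exclusion_threshold).all()
    ]
    kept = table[~table["subject_id"].isin(excluded)]

    rows = []
    for time_d, grp in kept.groupby("time_d"):
        if grp.empty:
            warnings.warn(f"time {time_d} d empty after exclusions; dropped")
            continue
        n = grp["subject_id"].nunique()
        gm = _geometric_mean(grp["fdp"].to_numpy())
        rows.append((time_d, n, gm, assign_fsd_weights(time_d, n, fsd_scheme)))
    if not rows:
        raise ValidationError("no time points retained after exclusions")
    rows.sort()
    times, n, gm, w = map(np.asarray, zip(*rows))
    dataset = CompositeDataset(times=times.astype(float), gm_fdp=gm.astype(float),
                               n=n.astype(int), fsd_weight=w.astype(float))
    return dataset, excluded


def group_plasma_mass(
    records: Sequence[SubjectRecord],
    *,
    at_time: float = 14.0,
    exclude: Iterable[str] = (),
    fallback_hematocrit: float | None = None,
) -> float:
    """Group plasma retinol mass M(5): geometric mean over subjects of
    (total retinol concentration at ``at_time``) x (plasma volume)."""
    exclude = set(exclude)
    if fallback_hematocrit is None:
        known = [r.hematocrit for r in records
                 if r.hematocrit is not None and not math.isnan(r.hematocrit)]
        fallback_hematocrit = float(np.mean(known)) if known else None
    masses = []
    for rec in records:
        if rec.subject_id in exclude:
            continue
        for time_d, _dh6, total in rec.samples:
            if time_d == at_time and total > 0:
                masses.append(compute_plasma_mass(total, rec.plasma_volume(fallback_hematocrit)))
    if not masses:
        raise ValidationError(f"no usable total-retinol samples at {at_time} d")
    return _geometric_mean(np.asarray(masses))


def read_subject_records(samples_csv, cohort_csv) -> list[SubjectRecord]:
    """Load the samples/cohort CSV pair into SubjectRecord objects.

    samples CSV: subject_id, time_d, dh6_retinol_umol_L, total_retinol_umol_L
    cohort CSV: subject_id, weight_kg, height_m, hematocrit, dose_umol
    """
    samples = pd.read_csv(samples_csv)
    cohort = pd.read_csv(cohort_csv)
    records = []
    for _, row in cohort.iterrows():
        sid = str(row["subject_id"])
        hct = row.get("hematocrit")
        hct = None if pd.isna(hct) else float(hct)
        rec = SubjectRecord(
            subject_id=sid,
            weight=float(row["weight_kg"]),
            height=float(row["height_m"]),
            hematocrit=hct,
            dose=float(row.get("dose_umol", DEFAULT_DOSE_UMOL)),
        )
        sub = samples[samples["subject_id"].astype(str) == sid]
        rec.samples = [
            (float(s["time_d"]), float(s["dh6_retinol_umol_L"]),
             float(s["total_retinol_umol_L"]))
            for _, s in sub.iterrows()
        ]
        records.append(rec)
    return [r for r in records if r.samples]
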