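"""Synthetic cohort generator.

Creates simulated women of reproductive age with known ("truth") kinetic
parameters, total body stores, anthropometry, sampling schedules, and
noisy tracer measurements, emulating the statistical structure of a
sparse-sampling community study: every subject sampled at day 14, half
at day 21 and half at 28, and each at one of 13 auxiliary times between
6 h and 91 d, with at most a configurable number of subjects per
auxiliary time.  Used to validate the composite-fitting and RID
pipeline end to end when no raw study data are available.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError
from .model import ModelParameters, reference_parameters, simulate_tracer, solve_steady_state
from .supersubject import AUXILIARY_TIMES, SubjectRecord, estimate_plasma_volume

__all__ = [
    "CohortConfig",
    "TrueSubject",
    "assign_schedule",
    "generate_cohort",
    "simulate_measurements",
    "cohort_frame",
    "truth_frame",
    "to_subject_records",
]


@dataclass
class CohortConfig:
    """Study-condition settings for the generator.

    Anthropometry moments follow the study population (weight 57 +/- 9.6
    kg, height 1.60 +/- 0.059 m); the dose is 6.84 µmol retinol
    equivalents; target stores are lognormal with geometric mean 965 µmol
    and a geometric SD wide enough to span roughly 250-3900 µmol across a
    cohort of 89.  Between-subject kinetic variation is multiplicative
    lognormal on the adjustable rate constants (the real dispersion is
    unknown: only composite data existed, so these defaults are
    placeholders for a plausible population).  Measurement noise is
    multiplicative lognormal on the tracer concentration.
    """

    n_subjects: int = 89
    dose_umol: float = 6.84
    weight_mean: float = 57.0
    weight_sd: float = 9.6
    height_mean: float = 1.60
    height_sd: float = 0.059
    hematocrit_mean: float = 0.38
    hematocrit_sd: float = 0.03
    retinol_mean: float = 1.5       # plasma retinol concentration, µmol/L
    retinol_sd: float = 0.25
    retinol_min: float = 0.5
    param_cv: float = 0.20          # between-subject CV of adjustable rates
    tbs_gm: float = 965.0           # target geometric-mean stores, µmol
    tbs_gsd: float = 1.7            # geometric SD of stores
    noise_cv: float = 0.10          # measurement noise CV
    aux_times: tuple[float, ...] = AUXILIARY_TIMES
    per_time_cap: int = 8
    include_implausible: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ConfigurationError("need at least 2 subjects")
        for name in ("weight_sd", "height_sd", "hematocrit_sd", "retinol_sd",
                     "param_cv", "noise_cv"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.per_time_cap < 1:
            raise ConfigurationError("per_time_cap must be >= 1")
        if self.tbs_gsd < 1.0:
            raise ConfigurationError("tbs_gsd must be >= 1")
        extra = set(self.aux_times) - set(AUXILIARY_TIMES)
        if extra:
            raise ConfigurationError(f"auxiliary times {sorted(extra)} not in the study design")
        self.aux_times = tuple(sorted(self.aux_times))

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        d["aux_times"] = list(self.aux_times)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CohortConfig":
        with open(path) as fh:
            d = json.load(fh)
        if "aux_times" in d:
            d["aux_times"] = tuple(d["aux_times"])
        return cls(**d)


@dataclass
class TrueSubject:
    """Ground truth for one simulated participant."""

    subject_id: str
    params: ModelParameters
    m5: float                  # plasma retinol mass, µmol
    true_tbs: float            # that subject's own steady-state M(6)+M(7)
    weight: float
    height: float
    hematocrit: float
    plasma_retinol: float      # µmol/L
    plasma_volume: float       # L
    dose: float
    times: tuple[float, float, float]


def assign_schedule(
    n_subjects: int,
    config: CohortConfig,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> list[tuple[float, float, float]]:
    """Assign each subject their three sampling times.

    Every subject gets day 14; subjects split as evenly as possible
    between days 21 and 28; the third time is dealt from random
    permutations of the auxiliary times (so successive subjects fill all
    times before any repeats), which keeps every auxiliary time at or
    below the per-time cap.
    """
    if n_subjects < 2:
        raise ConfigurationError("need at least 2 subjects")
    aux = list(config.aux_times)
    if n_subjects > len(aux) * config.per_time_cap:
        raise ConfigurationError(
            f"{n_subjects} subjects cannot respect a cap of {config.per_time_cap} "
            f"over {len(aux)} auxiliary times"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)

    # day 21 vs 28: random half split, sizes differing by at most 1
    order = rng.permutation(n_subjects)
    day21 = set(order[: n_subjects // 2 + (n_subjects % 2) * int(rng.integers(2))].tolist())

    aux_assignment: list[float] = []
    while len(aux_assignment) < n_subjects:
        aux_assignment.extend(rng.permutation(aux).tolist())
    aux_assignment = aux_assignment[:n_subjects]

    out = []
    for i in range(n_subjects):
        mid = 21.0 if i in day21 else 28.0
        out.append(tuple(sorted((14.0, mid, float(aux_assignment[i])))))
    return out


def _truncated_normal(rng, mean, sd, lo=-np.inf, hi=np.inf, max_tries=1000):
    """Redraw-based truncated normal; errors out after max_tries."""
    if sd == 0:
        if not (lo <= mean <= hi):
            raise ConfigurationError("degenerate truncated normal outside bounds")
        return mean
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    raise ConfigurationError(
        f"could not draw a value in [{lo}, {hi}] from N({mean}, {sd}) "
        f"after {max_tries} attempts"
    )


def _lognormal_multiplier(rng, cv):
    """Multiplicative factor with geometric mean 1 and the given CV."""
    if cv == 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return float(np.exp(rng.normal(0.0, sigma)))


def generate_cohort(
    config: CohortConfig,
    seed: int | None = None,
    *,
    base_params: ModelParameters | None = None,
) -> list[TrueSubject]:
    """Generate the cohort with per-subject truth.

    Each subject's adjustable rate constants are the group values times
    independent lognormal multipliers (geometric mean 1, CV
    ``param_cv``); her plasma mass comes from a drawn retinol
    concentration and her own Nadler plasma volume; stores heterogeneity
    is then induced by jointly rescaling L(5,6) and L(0,6) (preserving
    their ratio, hence the loss partition) so that her steady-state
    M(6)+M(7) hits a lognormal target with geometric mean ``tbs_gm``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if base_params is None:
        base_params, _ = reference_parameters()

    schedule = assign_schedule(config.n_subjects, config, rng=rng)
    log_gsd = math.log(config.tbs_gsd)

    subjects = []
    for i in range(config.n_subjects):
        weight = _truncated_normal(rng, config.weight_mean, config.weight_sd,
                                   lo=max(30.0, config.weight_mean - 3 * config.weight_sd),
                                   hi=config.weight_mean + 3 * config.weight_sd)
        height = _truncated_normal(rng, config.height_mean, config.height_sd,
                                   lo=max(1.30, config.height_mean - 3 * config.height_sd),
                                   hi=config.height_mean + 3 * config.height_sd)
        hct = _truncated_normal(rng, config.hematocrit_mean, config.hematocrit_sd,
                                lo=0.2, hi=0.55)
        conc = _truncated_normal(rng, config.retinol_mean, config.retinol_sd,
                                 lo=config.retinol_min,
                                 hi=config.retinol_mean + 4 * config.retinol_sd)
        pv = estimate_plasma_volume(height, weight, hct)
        m5 = conc * pv

        p = base_params
        updates = {
            name: p.l[key] * _lognormal_multiplier(rng, config.param_cv)
            for name, key in (
                ("L(5,4)", (5, 4)), ("L(6,5)", (6, 5)), ("L(5,6)", (5, 6)),
                ("L(7,5)", (7, 5)), ("L(5,7)", (5, 7)), ("L(0,6)", (0, 6)),
            )
        }
        dt3 = p.dt3 * _lognormal_multiplier(rng, config.param_cv)
        p_i = p.replace(dt3=dt3, **updates)

        # rescale the compartment-6 exit rates to hit this subject's target TBS
        target = None
        m7 = p_i.l[(7, 5)] * m5 / p_i.l[(5, 7)]
        for _ in range(1000):
            cand = float(config.tbs_gm * np.exp(rng.normal(0.0, log_gsd)))
            if cand > 1.05 * m7:
                target = cand
                break
        if target is None:
            raise ConfigurationError(
                "could not draw a target TBS above the fast-pool mass; "
                "check tbs_gm/tbs_gsd against the kinetic parameters"
            )
        m6_target = target - m7
        k6_needed = p_i.l[(6, 5)] * m5 / m6_target
        f = k6_needed / (p_i.l[(5, 6)] + p_i.l[(0, 6)])
        p_i = p_i.replace(**{
            "L(5,6)": p_i.l[(5, 6)] * f,
            "L(0,6)": p_i.l[(0, 6)] * f,
        })

        ss = solve_steady_state(p_i, m5)
        subjects.append(
            TrueSubject(
                subject_id=f"S{i + 1:03d}",
                params=p_i,
                m5=m5,
                true_tbs=ss.tbs,
                weight=weight,
                height=height,
                hematocrit=hct,
                plasma_retinol=conc,
                plasma_volume=pv,
                dose=config.dose_umol,
                times=schedule[i],
            )
        )
    return subjects


def simulate_measurements(
    cohort: Sequence[TrueSubject],
    config: CohortConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Noisy tracer measurements at each subject's assigned times.

    The labeled-retinol concentration is FDp x dose / plasma volume,
    multiplied by a lognormal error with geometric mean 1 and CV
    ``noise_cv``; the (noise-free) total retinol concentration is emitted
    alongside.  With ``include_implausible`` the first subject's tracer
    measurements are scaled down 100-fold to exercise the downstream
    exclusion screen.
    """
    if not cohort:
        raise ValidationError("empty cohort")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    rows = []
    for idx, subj in enumerate(cohort):
        times = np.asarray(sorted(subj.times))
        fdp = simulate_tracer(subj.params, times).fdp
        scale = 0.01 if (config.include_implausible and idx == 0) else 1.0
        for t, f in zip(times, fdp):
            noise = _lognormal_multiplier(rng, config.noise_cv)
            dh6 = f * subj.dose / subj.plasma_volume * noise * scale
            rows.append((subj.subject_id, float(t), dh6, subj.plasma_retinol))
    return pd.DataFrame(
        rows, columns=["subject_id", "time_d", "dh6_retinol_umol_L", "total_retinol_umol_L"]
    )


def cohort_frame(cohort: Sequence[TrueSubject]) -> pd.DataFrame:
    """Cohort CSV schema consumed by the composite builder."""
    return pd.DataFrame(
        [
            (s.subject_id, s.weight, s.height, s.hematocrit, s.dose)
            for s in cohort
        ],
        columns=["subject_id", "weight_kg", "height_m", "hematocrit", "dose_umol"],
    )


def truth_frame(cohort: Sequence[TrueSubject]) -> pd.DataFrame:
    """Ground-truth table for recovery scoring."""
    rows = []
    for s in cohort:
        d = {"subject_id": s.subject_id, "true_tbs": s.true_tbs, "m5": s.m5,
             "plasma_volume": s.plasma_volume}
        d.update({k: v for k, v in s.params.to_dict().items()})
        rows.append(d)
    return pd.DataFrame(rows)


def to_subject_records(
    cohort: Sequence[TrueSubject],
    measurements: pd.DataFrame,
) -> list[SubjectRecord]:
    """Bundle generator output into the analysis-side record objects."""
    by_subject = dict(tuple(measurements.groupby("subject_id")))
    records = []
    for s in cohort:
        sub = by_subject.get(s.subject_id)
        if sub is None:
            continue
        rec = SubjectRecord(
            subject_id=s.subject_id, weight=s.weight, height=s.height,
            hematocrit=s.hematocrit, dose=s.dose,
            samples=[
                (float(r["time_d"]), float(r["dh6_retinol_umol_L"]),
                 float(r["total_retinol_umol_L"]))
                for _, r in sub.iterrows()
            ],
        )
        records.append(rec)
    return records
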