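"""Synthetic patient-level cohort generator.

The source claims database behind the published cost figures is proprietary,
so this module generates cohorts with the same group-level statistical
structure: per-procedure patient counts and morbidity rates, right-skewed
costs matched by moments to the printed group mean/SD via a gamma
distribution, length of stay from a discretized log-normal matched to the
printed median and interquartile range, Bernoulli 30-day readmission at the
group rate, and a small fraction of records flagged with invalid cost data.
Demographics (age, gender, elective admission, Charlson index) are drawn
from per-group marginals only; no joint structure between cost, LOS and
readmission beyond shared group membership is modeled, because none is
reported.

Randomness is reproducible: a single integer seed governs all draws through
one numpy substream per (procedure, role) where role 0 assigns complication
status and roles 1/2 fill in the with/without-complication groups.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import stats

from ._rounding import round_half_up
from .cohort import PROCEDURES, PatientRecord

#: Standard-normal upper quartile; converts an IQR on the log scale to a
#: log-normal spread: sigma = (ln q75 - ln q25) / (2 * 0.6745).
_Z_QUARTILE = 0.6745


@dataclass
class ProcedureSpec:
    """Generating parameters for one procedure category.

    Costs are USD (group mean and SD), LOS quantiles are days, morbidity and
    readmission are probabilities.
    """

    procedure: str
    n: int
    morbidity: float
    cost_mean_with: float
    cost_sd_with: float
    cost_mean_without: float
    cost_sd_without: float
    los_median_with: float
    los_q25_with: float
    los_q75_with: float
    los_median_without: float
    los_q25_without: float
    los_q75_without: float
    readmit_with: float
    readmit_without: float

    def validate(self) -> None:
        if self.n <= 0:
            raise ValueError(f"{self.procedure}: n must be positive")
        for p, name in [(self.morbidity, "morbidity"),
                        (self.readmit_with, "readmit_with"),
                        (self.readmit_without, "readmit_without")]:
            if not 0 < p < 1:
                raise ValueError(f"{self.procedure}: {name} must be in (0,1), got {p}")
        for v, name in [(self.cost_mean_with, "cost_mean_with"),
                        (self.cost_sd_with, "cost_sd_with"),
                        (self.cost_mean_without, "cost_mean_without"),
                        (self.cost_sd_without, "cost_sd_without")]:
            if v <= 0:
                raise ValueError(f"{self.procedure}: {name} must be > 0")
        for q25, med, q75, grp in [
            (self.los_q25_with, self.los_median_with, self.los_q75_with, "with"),
            (self.los_q25_without, self.los_median_without, self.los_q75_without, "without"),
        ]:
            if not q25 <= med <= q75:
                raise ValueError(f"{self.procedure}: LOS quartiles out of order ({grp} group)")


@dataclass
class GroupMarginals:
    """Demographic marginals for one complication group."""

    age_mean: float
    age_sd: float
    pct_female: float
    pct_elective: float
    cci_mean: float


@dataclass
class CohortSpec:
    """Full generating specification for a ten-procedure surgical cohort."""

    procedures: dict[str, ProcedureSpec]
    invalid_cost_rate_with: float
    invalid_cost_rate_without: float
    marginals_with: GroupMarginals
    marginals_without: GroupMarginals
    seed: int = 0

    def validate(self) -> None:
        if not self.procedures:
            raise ValueError("spec has no procedures")
        for spec in self.procedures.values():
            spec.validate()
        for r in (self.invalid_cost_rate_with, self.invalid_cost_rate_without):
            if not 0 <= r < 1:
                raise ValueError(f"invalid-cost rate must be in [0,1), got {r}")

    @property
    def n_total(self) -> int:
        return sum(p.n for p in self.procedures.values())


# Published group-level parameters for the ten studied procedures:
# (n, morbidity, cost mean/SD with, cost mean/SD without,
#  LOS median/q25/q75 with, LOS median/q25/q75 without,
#  readmission rate with/without).
_DEFAULT_ROWS = {
    "AAA open repair": (2328, 0.649, 48002, 48841, 24619, 14543,
                        8, 6, 14, 6, 4, 7, 0.165, 0.087),
    "vascular bypass": (16336, 0.263, 31979, 30386, 16849, 12543,
                        6, 4, 9, 3, 2, 5, 0.213, 0.141),
    "esophagectomy": (690, 0.677, 67924, 65377, 37382, 17973,
                      13, 9, 20, 9, 8, 11, 0.185, 0.154),
    "gastrectomy": (25118, 0.202, 27794, 33530, 12641, 9452,
                    4, 2, 10, 2, 1, 2, 0.127, 0.052),
    "colectomy": (75121, 0.433, 27851, 29286, 14755, 10524,
                  8, 5, 11, 4, 3, 6, 0.152, 0.090),
    "resection of rectum": (10753, 0.336, 26916, 24466, 15979, 18855,
                            7, 5, 11, 5, 3, 6, 0.152, 0.104),
    "hepatectomy": (2362, 0.343, 37315, 38100, 20272, 13566,
                    7, 5, 11, 5, 3, 6, 0.179, 0.094),
    "pancreatectomy": (3569, 0.475, 50559, 46784, 27488, 19653,
                       11, 8, 18, 7, 5, 9, 0.261, 0.186),
    "cystectomy": (2552, 0.589, 41128, 38293, 25978, 15061,
                   10, 7, 14, 7, 6, 8, 0.292, 0.219),
    "F&H fracture repair": (65851, 0.385, 22218, 32644, 16805, 12167,
                            5, 4, 7, 4, 3, 5, 0.189, 0.174),
}

# Fractions of each group with valid cost data: 73,108 of 76,807
# complication patients and 127,398 of 127,873 without.
_VALID_COST_WITH = 73108 / 76807
_VALID_COST_WITHOUT = 127398 / 127873


def default_spec(seed: int = 0) -> CohortSpec:
    """The ten-procedure cohort at the published group-level parameters."""
    procedures = {}
    for name in PROCEDURES:
        (n, morb, cmw, csw, cmo, cso,
         lmw, lq25w, lq75w, lmo, lq25o, lq75o, rw, ro) = _DEFAULT_ROWS[name]
        procedures[name] = ProcedureSpec(
            procedure=name, n=n, morbidity=morb,
            cost_mean_with=cmw, cost_sd_with=csw,
            cost_mean_without=cmo, cost_sd_without=cso,
            los_median_with=lmw, los_q25_with=lq25w, los_q75_with=lq75w,
            los_median_without=lmo, los_q25_without=lq25o, los_q75_without=lq75o,
            readmit_with=rw, readmit_without=ro,
        )
    return CohortSpec(
        procedures=procedures,
        invalid_cost_rate_with=1.0 - _VALID_COST_WITH,
        invalid_cost_rate_without=1.0 - _VALID_COST_WITHOUT,
        marginals_with=GroupMarginals(68.8, 16.0, 0.584, 0.452, 2.2),
        marginals_without=GroupMarginals(62.4, 17.4, 0.590, 0.605, 1.5),
        seed=seed,
    )


def _lognormal_params(median: float, q25: float, q75: float) -> tuple[float, float]:
    mu = np.log(median)
    sigma = (np.log(q75) - np.log(max(q25, 1e-9))) / (2 * _Z_QUARTILE)
    return mu, max(sigma, 1e-9)


def _group_rng(seed: int, proc_index: int, role: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(proc_index, role)))


def _draw_group(rng: np.random.Generator, m: int, spec: ProcedureSpec,
                marg: GroupMarginals, invalid_rate: float, with_group: bool):
    if with_group:
        mean, sd = spec.cost_mean_with, spec.cost_sd_with
        med, q25, q75 = spec.los_median_with, spec.los_q25_with, spec.los_q75_with
        readmit_p = spec.readmit_with
    else:
        mean, sd = spec.cost_mean_without, spec.cost_sd_without
        med, q25, q75 = spec.los_median_without, spec.los_q25_without, spec.los_q75_without
        readmit_p = spec.readmit_without

    shape = (mean / sd) ** 2
    scale = sd ** 2 / mean
    cost = np.round(rng.gamma(shape, scale, size=m))
    mu, sigma = _lognormal_params(med, q25, q75)
    los = np.maximum(1, np.round(rng.lognormal(mu, sigma, size=m))).astype(int)
    readmit = rng.random(m) < readmit_p
    cost_valid = rng.random(m) >= invalid_rate
    a = (18.0 - marg.age_mean) / marg.age_sd
    age = stats.truncnorm.rvs(a, np.inf, loc=marg.age_mean, scale=marg.age_sd,
                              size=m, random_state=rng)
    female = rng.random(m) < marg.pct_female
    elective = rng.random(m) < marg.pct_elective
    cci = rng.poisson(marg.cci_mean, size=m)
    return cost, los, readmit, cost_valid, age, female, elective, cci


def generate_cohort(spec: CohortSpec, scale: float = 1.0) -> list[PatientRecord]:
    """Draw a patient-level cohort from ``spec``.

    ``scale`` shrinks every procedure's patient count (rounded, minimum 1)
    so desk-scale cohorts keep the full procedure mix. Generation is
    deterministic given ``spec.seed``.
    """
    if not 0 < scale <= 1:
        raise ValueError(f"scale must be in (0, 1], got {scale}")
    spec.validate()

    records: list[PatientRecord] = []
    for i, name in enumerate(spec.procedures):
        pspec = spec.procedures[name]
        m = max(1, round_half_up(pspec.n * scale))
        flags = _group_rng(spec.seed, i, 0).random(m) < pspec.morbidity
        idx_with = np.flatnonzero(flags)
        idx_without = np.flatnonzero(~flags)

        buf: list[PatientRecord | None] = [None] * m
        for role, idx, with_group, marg, invalid in (
            (1, idx_with, True, spec.marginals_with, spec.invalid_cost_rate_with),
            (2, idx_without, False, spec.marginals_without, spec.invalid_cost_rate_without),
        ):
            k = len(idx)
            if k == 0:
                continue
            rng = _group_rng(spec.seed, i, role)
            cost, los, readmit, cost_valid, age, female, elective, cci = _draw_group(
                rng, k, pspec, marg, invalid, with_group)
            for j, pos in enumerate(idx):
                buf[pos] = PatientRecord(
                    patient_id=f"P{i:02d}-{pos:06d}",
                    procedure=name,
                    age=float(np.round(age[j], 1)),
                    gender="female" if female[j] else "male",
                    elective=bool(elective[j]),
                    cci=int(cci[j]),
                    complication=with_group,
                    cost=float(cost[j]) if cost_valid[j] else None,
                    cost_valid=bool(cost_valid[j]),
                    los=int(los[j]),
                    readmit_30d=bool(readmit[j]),
                )
        records.extend(buf)  # position order: ids stable regardless of group split
    return records


# -- spec (de)serialization --------------------------------------------------

def spec_to_dict(spec: CohortSpec) -> dict:
    return dataclasses.asdict(spec)


def spec_from_dict(d: dict) -> CohortSpec:
    procedures = {k: ProcedureSpec(**v) for k, v in d["procedures"].items()}
    return CohortSpec(
        procedures=procedures,
        invalid_cost_rate_with=d["invalid_cost_rate_with"],
        invalid_cost_rate_without=d["invalid_cost_rate_without"],
        marginals_with=GroupMarginals(**d["marginals_with"]),
        marginals_without=GroupMarginals(**d["marginals_without"]),
        seed=d.get("seed", 0),
    )


def save_spec(spec: CohortSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False)


def load_spec(path) -> CohortSpec:
    with open(path) as fh:
        return spec_from_dict(yaml.safe_load(fh))
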