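"""Return on investment and bed-day opportunity cost.

Implementing goal-directed fluid therapy costs the hospital a disposable
sensor per patient plus the amortized share of a reusable cardiac-output
monitor. Comparing that per-patient cost with projected per-patient savings
gives a savings-per-dollar ratio. Separately, complications prolong stays,
so averting them frees bed-days that can admit new patients: days lost =
complications x mean excess LOS; days saved scale with the averted count;
freed days divided by the average LOS give new-admission capacity.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._rounding import round_half_up, round_half_up_to
from .projection import EffectSize, MorbidityProjection, StudyFrame, project_morbidity


@dataclass
class ImplementationCost:
    """Per-patient monitoring cost inputs (USD).

    Defaults: a US$250 disposable sensor plus a US$15,000 monitor used twice
    a week for 3 years (about US$48 amortization per use).
    """

    sensor_cost: float = 250.0
    monitor_price: float = 15_000.0
    uses_per_week: float = 2.0
    lifetime_years: float = 3.0
    weeks_per_year: float = 52.0

    def __post_init__(self) -> None:
        for name in ("sensor_cost", "monitor_price", "uses_per_week",
                     "lifetime_years", "weeks_per_year"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class BedDayProjection:
    days_lost: int
    days_saved_low: int
    days_saved_high: int
    new_patients_low: int
    new_patients_high: int
    new_patients_per_year_low: int
    new_patients_per_year_high: int


@dataclass
class RoiBedDayReport:
    impl_cost_per_patient: float
    impl_cost_per_patient_rounded: int
    amortization_per_use: float
    roi_low: float
    roi_high: float
    days_lost: int
    days_saved_low: int
    days_saved_high: int
    new_patients_low: int
    new_patients_high: int
    new_patients_per_year_low: int
    new_patients_per_year_high: int

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def implementation_cost_per_patient(cost: ImplementationCost) -> tuple[float, int]:
    """Per-patient implementation cost: sensor plus monitor amortization.

    Returns the exact value and its whole-dollar rounding.
    """
    uses = cost.uses_per_week * cost.weeks_per_year * cost.lifetime_years
    if uses == 0:
        raise ZeroDivisionError("monitor usage is zero: cannot amortize")
    exact = cost.sensor_cost + cost.monitor_price / uses
    return exact, round_half_up(exact)


def amortization_per_use(cost: ImplementationCost) -> float:
    return cost.monitor_price / (cost.uses_per_week * cost.weeks_per_year
                                 * cost.lifetime_years)


def roi_ratio(savings_per_patient_low: float, savings_per_patient_high: float,
              impl_cost_per_patient: float) -> tuple[float, float]:
    """Savings per dollar spent, per bound, to one decimal."""
    if impl_cost_per_patient <= 0:
        raise ValueError("implementation cost must be positive")
    return (round_half_up_to(savings_per_patient_low / impl_cost_per_patient, 1),
            round_half_up_to(savings_per_patient_high / impl_cost_per_patient, 1))


def project_bed_days(n_complications: int, effect: EffectSize,
                     excess_los: float = 3.0, avg_los: float = 5.0,
                     period_years: float = 2.5,
                     n_total: int | None = None) -> BedDayProjection:
    """Bed-days lost to complications and freed by averting them.

    Averted counts are rounded to integers before multiplying by the excess
    LOS, then new-patient capacity rounds half up at each step (days/avg_los,
    then per year). ``n_total`` is only needed for the odds-transform effect
    interpretation; count scaling needs the complication count alone.
    """
    if excess_los <= 0 or n_complications <= 0 or period_years <= 0:
        raise ValueError("n_complications, excess_los, period_years must be positive")
    if avg_los <= 0:
        raise ZeroDivisionError("avg_los must be positive")
    frame = StudyFrame(n_total=n_total if n_total is not None else n_complications,
                       n_complications=n_complications, cost_diff=0.0,
                       period_years=period_years)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        proj: MorbidityProjection = project_morbidity(frame, effect)
    averted_small = n_complications - proj.count_high
    averted_large = n_complications - proj.count_low
    days_lost = round_half_up(n_complications * excess_los)
    days_saved_low = round_half_up(averted_small * excess_los)
    days_saved_high = round_half_up(averted_large * excess_los)
    np_low = round_half_up(days_saved_low / avg_los)
    np_high = round_half_up(days_saved_high / avg_los)
    return BedDayProjection(
        days_lost=days_lost,
        days_saved_low=days_saved_low,
        days_saved_high=days_saved_high,
        new_patients_low=np_low,
        new_patients_high=np_high,
        new_patients_per_year_low=round_half_up(np_low / period_years),
        new_patients_per_year_high=round_half_up(np_high / period_years),
    )


def roi_bed_day_report(savings_per_patient_low: float,
                       savings_per_patient_high: float,
                       n_complications: int,
                       effect: EffectSize,
                       cost: ImplementationCost | None = None,
                       excess_los: float = 3.0, avg_los: float = 5.0,
                       period_years: float = 2.5,
                       n_total: int | None = None) -> RoiBedDayReport:
    """Combined ROI and bed-day report for one cohort and effect size."""
    cost = cost if cost is not None else ImplementationCost()
    exact, rounded = implementation_cost_per_patient(cost)
    roi_low, roi_high = roi_ratio(savings_per_patient_low,
                                  savings_per_patient_high, exact)
    beds = project_bed_days(n_complications, effect, excess_los=excess_los,
                            avg_los=avg_los, period_years=period_years,
                            n_total=n_total)
    return RoiBedDayReport(
        impl_cost_per_patient=exact,
        impl_cost_per_patient_rounded=rounded,
        amortization_per_use=amortization_per_use(cost),
        roi_low=roi_low, roi_high=roi_high,
        days_lost=beds.days_lost,
        days_saved_low=beds.days_saved_low,
        days_saved_high=beds.days_saved_high,
        new_patients_low=beds.new_patients_low,
        new_patients_high=beds.new_patients_high,
        new_patients_per_year_low=beds.new_patients_per_year_low,
        new_patients_per_year_high=beds.new_patients_per_year_high,
    )
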