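"""Return on investment and bed-day capacity.

Implementation costs: a $250 disposable sensor per patient plus the
amortized share of a $15,000 cardiac-output monitor used twice a week for
three years (~$48/use). The ROI ratio compares projected per-patient savings
with that cost. Separately, each complication prolongs the stay by ~3 days;
averting complications frees bed-days that, at a 5-day average stay, admit
new patients.
"""

from gdft_impact import EffectSize, ImplementationCost, roi_bed_day_report

report = roi_bed_day_report(
    savings_per_patient_low=754, savings_per_patient_high=1286,
    n_complications=76_807, effect=EffectSize(0.71, 0.83),
    cost=ImplementationCost(sensor_cost=250, monitor_price=15_000,
                            uses_per_week=2, lifetime_years=3),
    excess_los=3, avg_los=5, period_years=2.5)

print(f"implementation cost/patient: ${report.impl_cost_per_patient:.2f} "
      f"(amortization ${report.amortization_per_use:.2f}/use)")
print(f"savings per dollar spent:    {report.roi_low} - {report.roi_high}")
print(f"bed-days lost to complications: {report.days_lost:,}")
print(f"bed-days saved:              {report.days_saved_low:,} - "
      f"{report.days_saved_high:,}")
print(f"new patients admissible:     {report.new_patients_low:,} - "
      f"{report.new_patients_high:,} "
      f"({report.new_patients_per_year_low:,} - "
      f"{report.new_patients_per_year_high:,} per year)")
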