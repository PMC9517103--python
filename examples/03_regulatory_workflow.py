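"""The radon-protection decision chain for one worksite.

Screens a basement archive for radon potential, then walks the regulatory
workflow: measure, branch on the 300 Bq/m³ reference level, attempt
constructive mitigation, and fall back to operational mitigation (the
planner's dose-surveillance regime) when building works cannot fix it.
"""

from datetime import date

from radondose import (
    DoseParameters,
    WorkflowState,
    check_radon_potential,
    initial_workflow_state,
    next_workflow_state,
    Worksite,
)
from radondose.registry import LocationFlags

params = DoseParameters()
site = Worksite(
    site_id="ARCHIVE",
    name="basement archive",
    annual_mean_concentration=420.0,
    measurement_start=date(2024, 9, 1),
    measurement_end=date(2024, 12, 1),
    occupancy_hours_per_year=600.0,  # well over the 50 h/year threshold
    location_flags=LocationFlags(underground=True, radon_prone_area=True),
)

verdict = check_radon_potential(site, params)
print(f"radon potential: {verdict.has_potential}")
print(f"  occupancy over 50 h/year: {verdict.occupancy_ok}")
print(f"  triggered criteria: {', '.join(verdict.triggered_criteria)}")

state = initial_workflow_state(site, params)
print(f"\nworkflow: start -> {state.value}")

state = next_workflow_state(state, measured_concentration=420.0, params=params)
print(f"measured 420 Bq/m³ (> 300) -> {state.value}")

state = next_workflow_state(state, measured_concentration=380.0,
                            mitigation_feasible=True, params=params)
print(f"after works still 380 Bq/m³, further works feasible -> {state.value}")

state = next_workflow_state(state, measured_concentration=350.0,
                            mitigation_feasible=False, params=params)
print(f"still 350 Bq/m³, no feasible works left -> {state.value}")
assert state is WorkflowState.OPERATIONAL_MITIGATION
print("\noperational mitigation: manage doses by occupancy-time planning")
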