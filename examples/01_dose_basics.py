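"""Effective dose from radon concentration and occupancy time.

Computes the annual dose of a worker spending a full working year at the
300 Bq/m³ workplace reference level, then classifies a few annual doses
into the Directive 2013/59/Euratom worker categories.
"""

from radondose import DoseParameters, classify_annual_dose, effective_dose

params = DoseParameters()  # dose coefficient 6.7e-6 mSv/(Bq·h·m⁻³)

dose = effective_dose(concentration=300.0, hours=2000.0, params=params)
print(f"300 Bq/m³ for 2000 h/year -> {dose:.2f} mSv")
print("  (below the 6 mSv category-B ceiling: occupancy-time control alone")
print("   can keep a worker in category B at the reference level)")

for annual_dose, status in [(4.0, "standard"), (6.0, "standard"),
                            (8.5, "standard"), (0.9, "pregnant"), (1.0, "pregnant")]:
    a = classify_annual_dose(annual_dose, status, params)
    print(
        f"{annual_dose:5.1f} mSv/year, {status:10s} -> category {a.category.value:10s} "
        f"compliant={a.compliant}"
    )
# Category B covers doses up to and including 6 mSv; special statuses
# (pregnant, breastfeeding, minor) must stay strictly below 1 mSv.
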