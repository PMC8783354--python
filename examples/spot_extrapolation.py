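"""Estimate daily uEV excretion from a single spot urine.

A spot urine alone gives concentrations, not rates. Multiplying the
spot uEV/creatinine ratio by the subject's 24-h creatinine excretion
removes the unknown urine flow and yields an absolute daily excretion.
"""

from uevnorm import calculated_spot_excretion, uev_per_creatinine

spot_uev_conc = 1.0e10  # uEVs/L in the spot urine
spot_creat_conc = 5.0  # mmol/L creatinine in the same void
creat_excretion = 10.0  # mmol/day from the subject's 24-h collection

ratio = uev_per_creatinine(spot_uev_conc, spot_creat_conc)
rate = calculated_spot_excretion(spot_uev_conc, spot_creat_conc, creat_excretion)

print(f"spot uEV/creatinine ratio : {ratio:.3e} uEVs/mmol")
print(f"calculated excretion      : {rate.per_day:.3e} uEVs/day")
print(f"                          = {rate.per_min:.3e} uEVs/min")

# Dilution cancels: a 3x more dilute void gives the identical rate.
diluted = calculated_spot_excretion(spot_uev_conc / 3, spot_creat_conc / 3, creat_excretion)
print(f"after 3x dilution         : {diluted.per_day:.3e} uEVs/day (unchanged)")
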