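"""Dosimetry for one plan: DVH, D90, D2cm3, EQD2 and constraints.

Generates a synthetic plan with its dose grid, recomputes the DVH-based
metrics, converts the physical per-fraction doses to EQD2, and checks
the per-fraction organ constraints.
"""

from brachyqa.dosimetry import (
    EQD2Params,
    check_constraints,
    cumulative_dvh,
    dose_at_volume,
    dose_to_fraction,
    eqd2,
    plan_metrics,
)
from brachyqa.phantom import PhantomConfig, generate_plan
from brachyqa.structures import HRCTV

# keep_volumes retains the dose grid and masks on the record
rec = generate_plan(PhantomConfig(), plan_index=0, keep_volumes=True)

# Plans are normalized so the HR-CTV D90 equals the 7 Gy per-fraction
# prescription exactly.
dvh = cumulative_dvh(rec.dose, rec.structures.masks[HRCTV])
print(f"HR-CTV D90 = {dose_to_fraction(dvh, 0.90):.3f} Gy (prescription 7)")

m = plan_metrics(rec.dose, rec.structures)
verdicts = check_constraints(m)
print("\norgan             D2cm3 [Gy]   ratio   constraint")
for organ, d2 in m.d2cm3.items():
    print(f"{organ:16s}  {d2:8.3f}   {m.ratio[organ]:6.3f}   {verdicts[organ]}")

# D2cm3 straight from the DVH, for one organ, to show the primitive:
bl_dvh = cumulative_dvh(rec.dose, rec.structures.masks["bladder"])
print(f"\nbladder D2cm3 via dose_at_volume: {dose_at_volume(bl_dvh, 2.0):.3f} Gy")

# Biologically weighted total over a 4-fraction course (alpha/beta = 3 Gy
# for late-responding normal tissue, 10 Gy for the target):
bladder_eqd2 = eqd2(EQD2Params(n_fractions=4, d_per_fraction=m.d2cm3["bladder"],
                               alpha_beta=3.0))
target_eqd2 = eqd2(EQD2Params(n_fractions=4, d_per_fraction=m.d90_hrctv,
                              alpha_beta=10.0))
print(f"bladder D2cm3 EQD2 over 4 fractions: {bladder_eqd2:.1f} Gy")
print(f"HR-CTV D90 EQD2 over 4 fractions:    {target_eqd2:.1f} Gy")
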