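"""Score a hand-built five-visit ED log at a single timepoint.

Builds the tiny in-memory visit log shipped with the package, computes
the census metrics at 12:00 and prints all four crowding indices. The
mSEAL value is 1.49 + 9.72 x (bed-normalized trailing-hour patient
hours) + 0.18 x (mean hours to first physician contact), clamped to
[1, 6]; a value over 4.5 flags crowding.
"""

from datetime import datetime

from edload import compute_metrics, is_crowded, score_panel
from edload.simulate import TINY_PROFILE, TINY_VISITS

t = datetime(2017, 9, 1, 12, 0)
m = compute_metrics(TINY_VISITS, t, TINY_PROFILE)
panel = score_panel(TINY_VISITS, t, TINY_PROFILE)

print(f"at {t:%H:%M} with {TINY_PROFILE.treatment_beds} treatment beds:")
print(f"  census               {m.census}")
print(f"  patient hours        {m.patient_hours_raw:.2f} h raw, {m.patient_hours:.4f} normalized")
print(f"  time to MD           {m.time_to_md:.4f} h")
print(f"  mSEAL                {panel.mseal:.3f}  (crowded: {is_crowded(panel.mseal)})")
print(f"  occupancy rate       {panel.occupancy_rate:.2f}")
print(f"  NEDOCS (modified)    {panel.nedocs:.1f}")
print(f"  sICMED (modified)    {panel.sicmed} criteria met")
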