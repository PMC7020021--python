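"""Measure one simulated patient end to end.

Builds a phantom, applies a 3 mm Le Fort I advancement with 4 degrees of
clockwise rotation (soft-tissue response 0.627 mm/mm and 0.070 mm/degree),
then runs registration, QC, ROI volumetric subtraction and the cheek-mass
metric, printing every intermediate the clinical workflow reports.
"""

from cheekmorph import measure_patient
from cheekmorph.phantom import SurgeryParams, apply_surgery, make_phantom

pre = make_phantom()
post, truth = apply_surgery(pre, SurgeryParams(advancement=3.0,
                                               rotation_deg=4.0))

m = measure_patient("demo", pre.bone, pre.soft, post.bone, post.soft,
                    pre.landmarks, post.landmarks)

print(f"registration RMS: {m.rms_deviation:.4f} mm "
      f"(QC {'pass' if m.qc_pass else 'FAIL'}, <= 0.5 mm required)")
print(f"rotation change:  {m.rotation_change:+.2f} degrees "
      f"(applied {truth.rotation_deg:+.2f})")
for side in ("R", "L"):
    b, s = m.bone[side], m.soft[side]
    print(f"side {side}: bone dV={b.delta_volume:8.1f} mm3 over "
          f"{b.pre_area:7.1f} mm2 -> movement {b.movement:.3f} mm | "
          f"soft movement {s.movement:.3f} mm | "
          f"cheek mass {m.cheek_pre[side].position:+.2f} -> "
          f"{m.cheek_post[side].position:+.2f} mm vs cornea plane | "
          f"stratum {m.stratum[side]}")
print("\nNote: the measured bone movement exceeds the 3 mm translation "
      "because clockwise rotation about the incisor also carries the cheek "
      "bone anteriorly.")
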