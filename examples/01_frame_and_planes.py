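"""Build the anatomical frame and reference planes from a landmark set.

Generates a phantom landmark set, constructs the Frankfort-horizontal-based
coordinate frame and the full reference-plane set, and measures the
maxillary rotational angle (FH-occlusal dihedral).
"""

from cheekmorph import build_reference_frame, construct_planes, maxillary_rotation_angle
from cheekmorph.phantom import PhantomSpec, canonical_landmarks

lm = canonical_landmarks(PhantomSpec())
frame = build_reference_frame(lm)
planes = construct_planes(frame, lm)

print("frame origin (sella), mm:", frame.origin)
print("axes (x lateral-right, y anterior, z superior):")
print(frame.rotation)
for name in ("FH", "MSP", "OP", "ICP", "LCP_R", "MCP_R", "CPP_R"):
    p = planes[name]
    print(f"{name:6s} normal={p.normal.round(3)} offset={p.offset:7.2f} mm")

angle = maxillary_rotation_angle(frame, lm)
print(f"\nmaxillary rotational angle: {angle:.2f} degrees")
print("(the FH-occlusal plane dihedral; its post-minus-pre change is the"
      " clockwise rotation of the maxilla)")
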