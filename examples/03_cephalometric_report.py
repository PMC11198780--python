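"""Compute the 16 cephalometric characteristic measures from landmarks.

Given a full 46-landmark annotation, the package derives a patient-level
anatomical frame from the Frankfort horizontal plane (total-least-squares
fit through the Porions and Orbitales, oriented toward Nasion) and computes
distances, axis-projected vector components, and angles. Measures whose
input landmarks are missing are reported as unavailable, never silently
guessed.

Run:  python examples/03_cephalometric_report.py
"""

import numpy as np

from cephalo3d import LandmarkSet, frankfort_frame, measure_all, schema
from cephalo3d.phantom import full46_template

# The phantom template doubles as a fully annotated demonstration case.
ids = tuple(d.id for d in schema())
lms = LandmarkSet(full46_template(), ids)

frame = frankfort_frame(lms)
print("anatomical frame (unit vectors, world coordinates):")
print(f"  anterior: {np.round(frame.anterior, 3)}")
print(f"  superior: {np.round(frame.superior, 3)}")
print(f"  lateral : {np.round(frame.lateral, 3)}")

report = measure_all(lms)
print(f"\n{'measure':<36} {'value':>9}  units")
for mid, m in report.measures.items():
    value = f"{m.value:9.2f}" if m.available else "      n/a"
    print(f"{mid:<36} {value}  {m.units}")

# Robustness to partial annotations: drop one Porion — the Frankfort plane
# falls back to the remaining three points and every measure survives.
partial = LandmarkSet({k: v for k, v in lms.entries.items() if k != "PoL"}, ids)
r3 = measure_all(partial)
print(f"\nwith PoL missing: {sum(m.available for m in r3.measures.values())}/16 available")

# Drop an Orbitale too — frame-dependent measures become unavailable,
# point-to-point distances and angles that don't need the frame remain.
minimal = LandmarkSet(
    {k: v for k, v in lms.entries.items() if k not in ("PoL", "OrL")}, ids
)
r2 = measure_all(minimal)
unavailable = [mid for mid, m in r2.measures.items() if not m.available]
print(f"with PoL+OrL missing: unavailable -> {', '.join(unavailable)}")
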