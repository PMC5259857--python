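"""Measure one case: landmark coordinates in, 18 parameters out.

Builds a landmark file from the built-in template, reads it back the way a
clinical workflow would, and prints the 12 linear (mm) and 6 angular (deg)
parameters. The linear values depend on the calibration (here 127 PPI,
i.e. 0.2 mm per pixel); the angles are scale-free.
"""

from pathlib import Path
from tempfile import TemporaryDirectory

from cephkit import (
    CalibrationSpec,
    measure_all,
    read_landmarks,
    template_landmark_set,
    write_landmarks,
)

with TemporaryDirectory() as tmp:
    path = Path(tmp) / "patient.landmarks.json"
    write_landmarks(template_landmark_set(), path)

    landmarks = read_landmarks(path)
    calibration = CalibrationSpec.from_ppi(127)  # 25.4 / 127 = 0.2 mm/px

    print(f"case {landmarks.case_id!r}: {len(landmarks.points)} landmarks")
    for r in measure_all(landmarks, calibration):
        print(f"  {r.name:8s} {r.value:8.2f} {r.unit}")

print(
    "\nLinear values are physical distances between landmark pairs; "
    "SNA/SNB/ANB describe the sagittal jaw relationship, FMA and PP-MP "
    "the vertical skeletal pattern, NSAr the cranial-base flexure."
)
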