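"""Frame conventions, anatomical placements, and clinical sign conventions.

Global (navigation) frame, right-handed:

* **X** — mediolateral, positive to the subject's right,
* **Y** — vertical, positive up,
* **Z** — anteroposterior, positive forward (walking direction).

Segment frames coincide with the global frame in the neutral standing
posture, so every joint angle and both pelvic angles are zero at neutral.
Sagittal-plane motion is rotation about X; transverse-plane motion is
rotation about the vertical Y axis.

A rotation about +X maps +Y onto +Z ("top tips forward"), which fixes the
clinical signs below: e.g. hip flexion swings the thigh's distal end forward,
i.e. a *negative* rotation of the thigh about X relative to the pelvis.
"""

from __future__ import annotations

import math

import numpy as np

#: Standard gravity magnitude, m/s².
GRAVITY = 9.80665

#: Gravity vector in the global frame (points down), m/s².
GRAVITY_VEC = np.array([0.0, -GRAVITY, 0.0])

#: Unit vector a resting accelerometer reports in the global frame (up).
UP = np.array([0.0, 1.0, 0.0])

#: Default magnetic reference: unit vector, 60° inclination (down-forward).
#: Heading errors from this choice affect only the transverse component.
MAG_REFERENCE = np.array([0.0, -math.sin(math.radians(60.0)), math.cos(math.radians(60.0))])

#: The seven anatomical placements of the sensor network.
PLACEMENTS = (
    "pelvis",
    "thigh_l",
    "thigh_r",
    "shank_l",
    "shank_r",
    "foot_l",
    "foot_r",
)

#: Kinematic chain per side: (joint, proximal placement, distal placement).
CHAIN = {
    "l": (("hip_l", "pelvis", "thigh_l"), ("knee_l", "thigh_l", "shank_l"), ("ankle_l", "shank_l", "foot_l")),
    "r": (("hip_r", "pelvis", "thigh_r"), ("knee_r", "thigh_r", "shank_r"), ("ankle_r", "shank_r", "foot_r")),
}

#: Sign mapping from the raw sagittal (about-X) Euler component of the
#: relative rotation to the clinical angle: hip/knee flexion positive,
#: ankle dorsiflexion positive, pelvic anterior tilt positive.
SAGITTAL_SIGN = {
    "hip": -1.0,
    "knee": 1.0,
    "ankle": -1.0,
    "pelvic_tilt": 1.0,
}


def clinical_sign(joint: str) -> float:
    """Sign factor for a joint label such as ``"hip_l"`` or ``"knee"``."""
    base = joint.rsplit("_", 1)[0] if joint.endswith(("_l", "_r")) else joint
    return SAGITTAL_SIGN[base]


def side_of(placement: str) -> str | None:
    if placement.endswith("_l"):
        return "l"
    if placement.endswith("_r"):
        return "r"
    return None
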