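"""Base-pair and base-pair-step parameter algebra (mid-frame construction).

The rigid-body parameters relating two orthonormal triads follow the
CEHS/3DNA convention: the rotation from frame 1 to frame 2 factorises as
``Rz(t/2 - f) Ry(G) Rz(t/2 + f)`` where ``t`` is the twist, ``G`` the
roll-tilt magnitude and ``f`` its phase (roll = G cos f, tilt = G sin f);
the translation is expressed in the mid-frame.  ``compose_step`` and
``decompose_step`` are exact inverses of each other.

The same algebra yields intra-base-pair parameters when frame 1 is the
complementary-strand base frame flipped about its x-axis: then
(shift, slide, rise) read as (shear, stretch, stagger) and
(tilt, roll, twist) as (buckle, propeller, opening).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geom import rotation_about_axis, wrap_angle

__all__ = ["StepParameters", "compose_step", "decompose_step", "frames_about_mid"]

_EZ = np.array([0.0, 0.0, 1.0])
_EY = np.array([0.0, 1.0, 0.0])


@dataclass
class StepParameters:
    """Six rigid-body parameters for one dinucleotide step (or base pair).

    Angles in degrees, displacements in Å.
    """

    shift: float
    slide: float
    rise: float
    tilt: float
    roll: float
    twist: float

    def as_tuple(self):
        return (self.shift, self.slide, self.rise, self.tilt, self.roll, self.twist)


def _half_rotations(twist: float, roll: float, tilt: float):
    gamma = float(np.hypot(roll, tilt))
    phi = float(np.degrees(np.arctan2(tilt, roll))) if gamma > 0 else 0.0
    A = rotation_about_axis(_EZ, twist / 2 - phi) @ rotation_about_axis(_EY, gamma / 2) \
        @ rotation_about_axis(_EZ, phi)
    B = rotation_about_axis(_EZ, twist / 2 - phi) @ rotation_about_axis(_EY, gamma) \
        @ rotation_about_axis(_EZ, twist / 2 + phi)
    return A, B


def compose_step(R1: np.ndarray, o1: np.ndarray, params: StepParameters):
    """Frame 2 from frame 1 and the step parameters.

    Returns ``(R2, o2, Rm, om)`` including the mid-frame.
    """
    A, B = _half_rotations(params.twist, params.roll, params.tilt)
    Rm = R1 @ A
    R2 = R1 @ B
    disp = Rm @ np.array([params.shift, params.slide, params.rise])
    o2 = o1 + disp
    om = o1 + disp / 2.0
    return R2, o2, Rm, om


def decompose_step(R1: np.ndarray, o1: np.ndarray, R2: np.ndarray, o2: np.ndarray):
    """Step parameters relating frame 1 to frame 2 (inverse of compose_step).

    Returns ``(StepParameters, Rm, om)``.
    """
    z1, z2 = R1[:, 2], R2[:, 2]
    cg = float(np.clip(np.dot(z1, z2), -1.0, 1.0))
    g = float(np.degrees(np.arccos(cg)))
    hinge = np.cross(z1, z2)
    if np.linalg.norm(hinge) < 1e-12:
        # parallel z-axes: pure twist about the common axis
        x1, x2 = R1[:, 0], R2[:, 0]
        twist = float(np.degrees(np.arctan2(np.dot(np.cross(x1, x2), z1), np.dot(x1, x2))))
        roll = tilt = 0.0
        Rm = rotation_about_axis(z1, twist / 2.0) @ R1
    else:
        hinge = hinge / np.linalg.norm(hinge)
        R1p = rotation_about_axis(hinge, +g / 2.0) @ R1
        R2p = rotation_about_axis(hinge, -g / 2.0) @ R2
        zm = R1p[:, 2]
        x1p, x2p = R1p[:, 0], R2p[:, 0]
        twist = float(np.degrees(np.arctan2(np.dot(np.cross(x1p, x2p), zm), np.dot(x1p, x2p))))
        Rm = rotation_about_axis(zm, twist / 2.0) @ R1p
        ym = Rm[:, 1]
        phi = float(np.degrees(np.arctan2(np.dot(np.cross(hinge, ym), zm), np.dot(hinge, ym))))
        roll = g * float(np.cos(np.radians(phi)))
        tilt = g * float(np.sin(np.radians(phi)))
    local = Rm.T @ (o2 - o1)
    om = (o1 + o2) / 2.0
    params = StepParameters(shift=float(local[0]), slide=float(local[1]), rise=float(local[2]),
                            tilt=tilt, roll=roll, twist=twist)
    return params, Rm, om


def frames_about_mid(Rm: np.ndarray, om: np.ndarray, params: StepParameters):
    """Invert the mid-frame: the pair of frames whose mid-frame is (Rm, om)
    and whose relating parameters are ``params``.  Returns (R1, o1, R2, o2)."""
    A, B = _half_rotations(params.twist, params.roll, params.tilt)
    R1 = Rm @ A.T
    R2 = R1 @ B
    disp = Rm @ np.array([params.shift, params.slide, params.rise])
    o1 = om - disp / 2.0
    o2 = om + disp / 2.0
    return R1, o1, R2, o2
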