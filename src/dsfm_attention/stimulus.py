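"""Disparity-rendered structure-from-motion (dSFM) cylinder stimuli.

A cylinder is a field of dots on the surface of a transparent vertical
cylinder rotating about its own axis.  Each dot is parameterized by a phase
``theta`` around the axis and a vertical position ``y``.  On screen the dot
appears at ``x = R * sin(theta)`` with horizontal speed ``R * omega *
cos(theta)`` — fastest at the midline, zero at the edges — so the projected
motion is two opposite-moving sheets of dots.  That 2-D motion is identical
for clockwise and counter-clockwise rotation; only the binocular disparity
assigns a depth order.  Disparity follows the same cosine profile,
``s * disparity_max * cos(theta)``, with the sign ``s`` set by the rotation
direction: positive (near, crossed) disparity attaches to the
rightward-moving sheet for counter-clockwise rotation, the reverse for
clockwise, and ``s = 0`` for a perceptually ambiguous cylinder.

Dots have a short lifetime: on every video frame a fixed fraction is deleted
and replotted at a random position with the velocity and disparity of the
new location, which keeps the percept driven by short-range motion and depth
cues rather than long dot trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StimulusParams",
    "CylinderField",
    "StereoFrame",
    "init_field",
    "project_dot",
    "step_field",
    "render_stereo",
    "rotation_period",
    "make_cylinder_pair",
    "simulate_frames",
    "frames_to_table",
]

DIRECTIONS = ("clockwise", "counterclockwise", "ambiguous")

#: disparity sign per rotation direction.  Positive disparity = near
#: (crossed); it is carried by the rightward-moving sheet (cos(theta) > 0)
#: for counter-clockwise rotation when the cylinder is viewed from above.
_DISPARITY_SIGN = {"counterclockwise": 1.0, "clockwise": -1.0, "ambiguous": 0.0}


@dataclass(frozen=True)
class StimulusParams:
    """Geometry and dynamics of one dSFM cylinder.

    Angular speed is rotation about the cylinder axis in degrees of rotation
    per second (so the rotation period is ``360 / angular_speed`` seconds);
    conversion to on-screen visual degrees per second passes through the
    cylinder radius ``R = field_width / 2``.
    """

    field_width: float = 5.0       # degrees of visual angle
    field_height: float = 5.0      # degrees
    n_dots: int = 125
    dot_size: float = 0.2          # degrees; metadata only, dots are points here
    disparity_max: float = 0.09    # degrees, center-to-front
    angular_speed: float = 138.5   # degrees of rotation / s (stimulus range 100-177)
    frame_rate: float = 100.0      # Hz (projector frame rate)
    replot_fraction: float = 0.02  # per-frame replot probability per dot
    center_offset: tuple[float, float] = (0.0, 0.0)  # (x, y) degrees from fixation
    direction: str = "counterclockwise"

    def __post_init__(self) -> None:
        if self.n_dots <= 0:
            raise ValueError("n_dots must be positive")
        if self.field_height <= 0 or self.field_width <= 0:
            raise ValueError("field dimensions must be positive")
        if self.disparity_max < 0:
            raise ValueError("disparity_max must be non-negative")
        if not 0.0 <= self.replot_fraction <= 1.0:
            raise ValueError("replot_fraction must lie in [0, 1]")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")

    @property
    def radius(self) -> float:
        return self.field_width / 2.0

    @property
    def omega(self) -> float:
        """Angular speed in radians of rotation per second."""
        return math.radians(self.angular_speed)

    @property
    def disparity_sign(self) -> float:
        return _DISPARITY_SIGN[self.direction]


@dataclass
class CylinderField:
    """Per-dot state of one cylinder at one instant."""

    theta: np.ndarray     # phase around the axis, radians in [0, 2*pi)
    y: np.ndarray         # vertical position, degrees within the field
    white: np.ndarray     # dot polarity; True = white, False = black
    age: np.ndarray       # frames since the dot was (re)plotted

    @property
    def n_dots(self) -> int:
        return self.theta.shape[0]

    def copy(self) -> "CylinderField":
        return CylinderField(self.theta.copy(), self.y.copy(),
                             self.white.copy(), self.age.copy())


@dataclass
class StereoFrame:
    """One rendered stereo frame: per-dot eye positions and kinematics.

    ``x_left - x_right = disparity`` for every dot (positive = near/crossed),
    so the eye-image separation equals the disparity magnitude.
    """

    x_left: np.ndarray    # left-eye horizontal position, degrees from fixation
    x_right: np.ndarray   # right-eye horizontal position
    y: np.ndarray         # vertical position, degrees from fixation
    speed: np.ndarray     # signed on-screen horizontal speed, degrees / s
    disparity: np.ndarray # signed disparity, degrees


def project_dot(theta, params: StimulusParams):
    """Project cylinder phase(s) to screen position, speed and disparity.

    Returns ``(x, speed, disparity)``; accepts scalars or arrays.
    ``x = R sin(theta)``, ``speed = R omega cos(theta)`` (omega in rad/s),
    ``disparity = s * disparity_max * cos(theta)``.  Peak speed and
    disparity occur at the cylinder midline and fall to zero at the edges.
    """
    theta = np.asarray(theta, dtype=float)
    c = np.cos(theta)
    x = params.radius * np.sin(theta)
    speed = params.radius * params.omega * c
    disparity = params.disparity_sign * params.disparity_max * c
    return x, speed, disparity


def rotation_period(angular_speed: float) -> float:
    """Seconds for one full 360-degree rotation at the given angular speed."""
    if angular_speed <= 0:
        raise ValueError("angular_speed must be positive")
    return 360.0 / angular_speed


def init_field(params: StimulusParams, seed: int) -> CylinderField:
    """Create a fresh dot field.

    Phases are uniform on [0, 2*pi).  Vertical positions are stratified
    uniformly over the field height (one dot per row of spacing
    ``height / n_dots``) with a +-0.5-row uniform jitter so no regular
    pattern appears, then randomly assigned to dots.  Polarity is split
    half/half white and black at random.
    """
    rng = np.random.default_rng(seed)
    n = params.n_dots
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    spacing = params.field_height / n
    rows = (np.arange(n) + 0.5) * spacing - params.field_height / 2.0
    y = rows + rng.uniform(-0.5, 0.5, size=n) * spacing
    y = rng.permutation(y)
    white = np.zeros(n, dtype=bool)
    white[rng.permutation(n)[: n // 2]] = True
    return CylinderField(theta=theta, y=y, white=white, age=np.zeros(n, dtype=int))


def step_field(field: CylinderField, params: StimulusParams,
               dt: float | None = None,
               rng: np.random.Generator | None = None) -> CylinderField:
    """Advance the field by one frame.

    Surviving dots rotate by ``omega * dt`` (phase wrap-around at 2*pi is the
    edge wrap: the dot reappears on the opposite-moving sheet with the
    matching velocity and disparity gradient, and keeps its age).  A random
    ``replot_fraction`` subset is deleted and replotted uniformly in
    ``(theta, y)`` with age reset to zero.  Dot count is conserved.
    """
    if dt is None:
        dt = 1.0 / params.frame_rate
    if rng is None:
        rng = np.random.default_rng()
    theta = np.mod(field.theta + params.omega * dt, 2.0 * np.pi)
    y = field.y.copy()
    age = field.age + 1
    if params.replot_fraction > 0.0:
        replot = rng.random(field.n_dots) < params.replot_fraction
        k = int(replot.sum())
        if k:
            theta[replot] = rng.uniform(0.0, 2.0 * np.pi, size=k)
            y[replot] = rng.uniform(-params.field_height / 2.0,
                                    params.field_height / 2.0, size=k)
            age[replot] = 0
    return CylinderField(theta=theta, y=y, white=field.white.copy(), age=age)


def render_stereo(field: CylinderField, params: StimulusParams) -> StereoFrame:
    """Render the field as a stereo pair.

    Sign convention (the single place it is defined): signed disparity
    ``delta`` is positive for near (crossed) disparity, and the half-split is
    ``x_left = x + delta / 2``, ``x_right = x - delta / 2``, so
    ``x_left - x_right = delta`` and zero disparity gives identical eye
    images.  Coordinates are offset by the cylinder's ``center_offset``.
    """
    x, speed, disparity = project_dot(field.theta, params)
    cx, cy = params.center_offset
    x = x + cx
    return StereoFrame(
        x_left=x + disparity / 2.0,
        x_right=x - disparity / 2.0,
        y=field.y + cy,
        speed=speed,
        disparity=disparity,
    )


def make_cylinder_pair(params_left: StimulusParams | None = None,
                       params_right: StimulusParams | None = None,
                       seed_left: int = 0,
                       seed_right: int = 1) -> tuple[CylinderField, CylinderField]:
    """Two independent cylinders at mirrored horizontal offsets.

    Defaults place the centers at (-5.5, -4.5) and (+5.5, -4.5) degrees.
    The two fields use independent seeds; re-seeding per trial puts the dots
    in new positions from one trial to the next.
    """
    if params_left is None:
        params_left = StimulusParams(center_offset=(-5.5, -4.5))
    if params_right is None:
        params_right = StimulusParams(center_offset=(+5.5, -4.5))
    return init_field(params_left, seed_left), init_field(params_right, seed_right)


def simulate_frames(params: StimulusParams, n_frames: int, seed: int) -> list[StereoFrame]:
    """Run a cylinder for ``n_frames`` frames and render every frame."""
    ss = np.random.SeedSequence(seed)
    init_seed, step_seed = ss.spawn(2)
    field = init_field(params, seed=init_seed.generate_state(1)[0] % (2**31))
    rng = np.random.default_rng(step_seed)
    frames = [render_stereo(field, params)]
    for _ in range(n_frames - 1):
        field = step_field(field, params, rng=rng)
        frames.append(render_stereo(field, params))
    return frames


def frames_to_table(frames: list[StereoFrame]) -> pd.DataFrame:
    """Long-format coordinate export, one row per frame x dot x eye."""
    rows = []
    for i, fr in enumerate(frames):
        n = fr.y.shape[0]
        for eye, x in (("left", fr.x_left), ("right", fr.x_right)):
            rows.append(pd.DataFrame({
                "frame": i,
                "dot_id": np.arange(n),
                "eye": eye,
                "x_deg": x,
                "y_deg": fr.y,
                "disparity_deg": fr.disparity,
                "speed_deg_per_s": fr.speed,
            }))
    return pd.concat(rows, ignore_index=True)
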