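"""Two-axis rotating-bed conventions and gravity-alignment solving.

The treatment bed rotates the prone patient about two axes:

* ``theta_x`` — rotation about the bed's lateral axis (bed X-hat, toward the
  prone patient's right), range −90°…+90°.  Positive tips the patient toward
  the standing position (head up); negative inverts (head down).
* ``theta_y`` — rotation about the bed's longitudinal axis (bed Y-hat, toward
  the head), range −60°…+60°.  Positive overturns to the right, negative to
  the left.

At neutral (0, 0) the bed Z-hat points up, so world gravity expressed in the
bed-fixed frame is (0, 0, −1).  The bed-to-world rotation is composed as
``R = R_lateral(theta_x) @ R_longitudinal(theta_y)`` (outer gimbal = X), and
gravity in the bed frame is ``g_b = R.T @ (0, 0, -1)``, which reduces to the
closed form::

    g_b = ( sin(theta_y) * cos(theta_x),
            -sin(theta_x),
            -cos(theta_y) * cos(theta_x) )

Anchors pinning the sign convention: g_b(+90, 0) = (0, −1, 0) — gravity
toward the feet, standing; g_b(−90, 0) = (0, +1, 0) — inverted; a positive
``theta_y`` gives gravity a positive lateral component (right side down).

All anatomy coordinates elsewhere in the package live in this bed frame, in
millimetres, with cranial = +Y-hat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "THETA_X_LIMIT",
    "THETA_Y_LIMIT",
    "BedOrientation",
    "BedFrameConvention",
    "BedLimitError",
    "InvalidDirectionError",
    "BedAngleSolution",
    "rotation_matrix",
    "gravity_in_bed_frame",
    "solve_bed_angles",
]

#: Hardware rotation limits of the bed, degrees.
THETA_X_LIMIT = 90.0
THETA_Y_LIMIT = 60.0

#: Default alignment tolerance (degrees) below which a solution counts as feasible.
DEFAULT_ALIGNMENT_TOLERANCE = 1.0


class BedLimitError(ValueError):
    """An angle outside the bed's hardware rotation range."""


class InvalidDirectionError(ValueError):
    """A target direction that is not a usable unit vector."""


@dataclass(frozen=True)
class BedOrientation:
    """One (theta_x, theta_y) bed angle pair, degrees, within hardware limits."""

    theta_x: float
    theta_y: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.theta_x) or not math.isfinite(self.theta_y):
            raise BedLimitError("bed angles must be finite")
        if abs(self.theta_x) > THETA_X_LIMIT + 1e-9:
            raise BedLimitError(
                f"theta_x={self.theta_x:.3f} outside X-axis range "
                f"[-{THETA_X_LIMIT:.0f}, +{THETA_X_LIMIT:.0f}] degrees"
            )
        if abs(self.theta_y) > THETA_Y_LIMIT + 1e-9:
            raise BedLimitError(
                f"theta_y={self.theta_y:.3f} outside Y-axis range "
                f"[-{THETA_Y_LIMIT:.0f}, +{THETA_Y_LIMIT:.0f}] degrees"
            )

    def as_tuple(self) -> tuple[float, float]:
        return (self.theta_x, self.theta_y)


@dataclass(frozen=True)
class BedFrameConvention:
    """The global right-handed bed frame; immutable within a run.

    lateral_axis is bed X-hat (prone patient's right), longitudinal_axis is
    bed Y-hat (toward the head), vertical_axis is bed Z-hat (up at neutral).
    Composition order is fixed: the lateral (X) rotation is the outer gimbal.
    """

    lateral_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    longitudinal_axis: tuple[float, float, float] = (0.0, 1.0, 0.0)
    vertical_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    composition_order: str = "X_then_Y"

    def __post_init__(self) -> None:
        m = np.array([self.lateral_axis, self.longitudinal_axis, self.vertical_axis])
        if not np.allclose(m @ m.T, np.eye(3), atol=1e-12) or not np.isclose(
            np.linalg.det(m), 1.0, atol=1e-12
        ):
            raise ValueError("bed frame axes must form a right-handed orthonormal triad")
        if self.composition_order != "X_then_Y":
            raise ValueError("only composition_order='X_then_Y' is supported")


def _rot_x(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _rot_y(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rotation_matrix(orientation: BedOrientation) -> np.ndarray:
    """Bed-to-world rotation R = R_x(theta_x) @ R_y(theta_y)."""
    return _rot_x(orientation.theta_x) @ _rot_y(orientation.theta_y)


def gravity_in_bed_frame(orientation: BedOrientation) -> np.ndarray:
    """World gravity direction expressed in the bed-fixed frame (unit vector).

    Equals ``rotation_matrix(orientation).T @ (0, 0, -1)``; the closed form is
    used for speed and exactness.
    """
    tx = math.radians(orientation.theta_x)
    ty = math.radians(orientation.theta_y)
    return np.array(
        [
            math.sin(ty) * math.cos(tx),
            -math.sin(tx),
            -math.cos(ty) * math.cos(tx),
        ]
    )


def gravity_grid(theta_x: np.ndarray, theta_y: np.ndarray) -> np.ndarray:
    """Vectorised ``gravity_in_bed_frame`` over arrays of angles (degrees).

    Returns an array of shape ``theta_x.shape + (3,)``.  No limit checking —
    intended for grid searches and minimax orientation optimisation.
    """
    tx = np.radians(np.asarray(theta_x, dtype=float))
    ty = np.radians(np.asarray(theta_y, dtype=float))
    return np.stack(
        [np.sin(ty) * np.cos(tx), -np.sin(tx), -np.cos(ty) * np.cos(tx)], axis=-1
    )


@dataclass(frozen=True)
class BedAngleSolution:
    """Result of the inverse problem: align gravity with a target direction."""

    orientation: BedOrientation
    residual: float  #: angle (degrees) between achieved gravity and the target
    feasible: bool  #: residual <= the alignment tolerance

    def as_tuple(self) -> tuple[float, float]:
        return self.orientation.as_tuple()


def _angle_between_deg(u: np.ndarray, v: np.ndarray) -> float:
    # atan2 of cross/dot is well-conditioned near 0 and 180 degrees, where
    # acos(dot) loses half the significant digits
    return math.degrees(
        math.atan2(float(np.linalg.norm(np.cross(u, v))), float(np.dot(u, v)))
    )


def _best_theta_x(a: float, b: float) -> float:
    """Maximise a*cos(tx) + b*sin(tx) over tx in [-90, 90] degrees."""
    phi = math.degrees(math.atan2(b, a))
    if abs(phi) <= THETA_X_LIMIT:
        return phi
    # unconstrained optimum out of range: compare the two endpoints
    return THETA_X_LIMIT if b >= 0 else -THETA_X_LIMIT


def solve_bed_angles(
    target_direction: np.ndarray,
    alignment_tolerance: float = DEFAULT_ALIGNMENT_TOLERANCE,
) -> BedAngleSolution:
    """Find the in-range bed orientation whose gravity best matches a target.

    Solves ``argmin_(theta_x, theta_y) angle(g_b(theta_x, theta_y), t)`` over
    the hardware rectangle |theta_x| <= 90, |theta_y| <= 60.  When the target
    lies in the reachable set the closed-form exact solution is returned with
    residual < 1e-6 degrees; otherwise the orientation is clamped to the
    boundary that minimises the residual and ``feasible`` is False unless the
    residual still falls under ``alignment_tolerance``.

    Ties at degenerate targets (e.g. pure head/foot gravity, where theta_y is
    irrelevant) are broken toward the smallest |theta_x|, then smallest
    |theta_y|.

    Raises
    ------
    InvalidDirectionError
        If the target has (near-)zero norm or is not close to unit length.
    """
    t = np.asarray(target_direction, dtype=float)
    if t.shape != (3,) or not np.all(np.isfinite(t)):
        raise InvalidDirectionError("target direction must be a finite 3-vector")
    norm = float(np.linalg.norm(t))
    if norm < 1e-12:
        raise InvalidDirectionError("target direction has zero norm")
    if abs(norm - 1.0) > 1e-6:
        raise InvalidDirectionError(
            f"target direction must be unit length (|t| = {norm:.8f})"
        )
    t = t / norm
    tx_comp, ty_comp, tz_comp = t

    # Exact inversion: g_b = (sin ty cos tx, -sin tx, -cos ty cos tx) with
    # cos tx >= 0 for tx in [-90, 90].
    horiz = math.hypot(tx_comp, tz_comp)
    theta_x_exact = math.degrees(math.atan2(-ty_comp, horiz))
    if horiz < 1e-12:
        theta_y_exact = 0.0  # theta_y irrelevant: pick the smallest magnitude
    else:
        theta_y_exact = math.degrees(math.atan2(tx_comp, -tz_comp))

    candidates: list[BedOrientation] = []
    if abs(theta_y_exact) <= THETA_Y_LIMIT:
        candidates.append(BedOrientation(theta_x_exact, theta_y_exact))
    # Clamped-theta_y candidates: for fixed theta_y the dot with the target is
    # A cos(tx) + B sin(tx) with A = tx_comp sin(ty) - tz_comp cos(ty), B = -ty_comp.
    for ty_c in (THETA_Y_LIMIT, -THETA_Y_LIMIT):
        ty_r = math.radians(ty_c)
        a = tx_comp * math.sin(ty_r) - tz_comp * math.cos(ty_r)
        candidates.append(BedOrientation(_best_theta_x(a, -ty_comp), ty_c))

    scored: list[tuple[float, BedOrientation]] = [
        (_angle_between_deg(gravity_in_bed_frame(o), t), o) for o in candidates
    ]
    best_residual = min(r for r, _ in scored)
    # At |theta_x| = 90 the gravity direction is independent of theta_y: add the
    # tie-preferred theta_y = 0 variant before applying the tie-break.
    extra = [
        BedOrientation(o.theta_x, 0.0)
        for r, o in scored
        if abs(abs(o.theta_x) - THETA_X_LIMIT) < 1e-9
    ]
    scored += [(_angle_between_deg(gravity_in_bed_frame(o), t), o) for o in extra]

    eligible = [(r, o) for r, o in scored if r <= best_residual + 1e-9]
    eligible.sort(key=lambda ro: (abs(ro[1].theta_x), abs(ro[1].theta_y)))
    residual, orientation = eligible[0]
    return BedAngleSolution(
        orientation=orientation,
        residual=residual,
        feasible=residual <= alignment_tolerance,
    )
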