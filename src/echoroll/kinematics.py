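"""3D head-pose mathematics for the echolocation model.

Frames and sign conventions (the single convention table for the package):

* Body frame B and head frame H are right-handed with **X forward, Y left,
  Z up**.  The head direction is the head-frame X axis (the roll axis).
* Positive yaw turns the head leftward (toward +Y), positive pitch raises
  it (toward +Z), positive torsion/roll brings the right ear down.
* ``elementary_rotation`` returns *active* rotation matrices under these
  conventions: about X and Z they are the usual right-handed rotations;
  about Y the sign is flipped so that a positive pitch tilts the X axis
  upward (equivalently, a right-handed rotation about -Y).
* A head pose is the Fick composition ``R_HB = R_Z(yaw) R_Y(pitch)
  R_X(torsion)`` mapping head coordinates to body coordinates; its
  transpose ``R_BH`` maps body to head coordinates and is the matrix that
  transforms the sound-source direction into head-centred coordinates.
* The incremental update of the accumulated body-to-head matrix treats
  the per-iteration yaw/pitch commands as passive rotations, so a positive
  yaw command moves the head direction toward positive azimuth.

Directions are represented either as unit 3-vectors or as angle triples
(azimuth theta, elevation phi, horizontal alpha), where the horizontal
angle satisfies ``alpha = asin(sin theta * cos phi)`` and is the coordinate
in which head-related transfer functions are gridded (it is constant on a
cone of confusion around the interaural axis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FickAngles",
    "DirectionAngles",
    "GimbalLockError",
    "CollinearMarkersError",
    "elementary_rotation",
    "horizontal_angle",
    "azimuth_from_horizontal",
    "direction_from_angles",
    "direction_from_horizontal",
    "angles_from_direction",
    "update_head_rotation",
    "listing_torsion",
    "head_pose_with_roll",
    "fick_decompose",
    "target_in_head_coords",
    "estimate_pose_from_markers",
    "read_marker_csv",
    "poses_to_csv",
]

_ORTHO_TOL = 1e-9
_GIMBAL_TOL_DEG = 1e-6


class GimbalLockError(ValueError):
    """Fick decomposition is undefined at |pitch| = 90 deg."""


class CollinearMarkersError(ValueError):
    """The three motion-capture markers do not span a plane."""


@dataclass(frozen=True)
class FickAngles:
    """Fick-gimbal head pose: yaw, pitch, torsion in degrees.

    The gimbal order is yaw-then-pitch-then-torsion (R_Z R_Y R_X).
    """

    yaw: float
    pitch: float
    torsion: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.yaw, self.pitch, self.torsion)


@dataclass(frozen=True)
class DirectionAngles:
    """A direction as azimuth/elevation plus the derived horizontal angle.

    All angles in degrees.  ``horizontal = asin(sin(azimuth) *
    cos(elevation))``.
    """

    azimuth: float
    elevation: float

    @property
    def horizontal(self) -> float:
        return horizontal_angle(self.azimuth, self.elevation)


def _check_rotation(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError(f"rotation matrix must be 3x3, got {R.shape}")
    if not np.all(np.isfinite(R)):
        raise ValueError("rotation matrix contains non-finite entries")
    err = np.abs(R.T @ R - np.eye(3)).max()
    if err > 1e-6:
        raise ValueError(f"matrix is not orthonormal (deviation {err:.2e})")
    if np.linalg.det(R) < 0:
        raise ValueError("matrix is a reflection, not a rotation")
    return R


def _orthonormalize(R: np.ndarray) -> np.ndarray:
    """Project onto SO(3) (nearest rotation, via SVD)."""
    U, _, Vt = np.linalg.svd(R)
    out = U @ Vt
    if np.linalg.det(out) < 0:
        out = U @ np.diag([1.0, 1.0, -1.0]) @ Vt
    return out


def elementary_rotation(axis: str, angle_deg: float) -> np.ndarray:
    """Active rotation matrix about a body axis.

    Parameters
    ----------
    axis : {"X", "Y", "Z"}
        Body axis (X forward, Y left, Z up).
    angle_deg : float
        Rotation angle in degrees.  Positive Z = leftward yaw, positive
        Y = upward pitch, positive X = right-ear-down roll.
    """
    if not np.isfinite(angle_deg):
        raise ValueError("rotation angle must be finite")
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    axis = axis.upper()
    if axis == "X":
        return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])
    if axis == "Y":
        # elevation-positive-up convention: right-handed about -Y
        return np.array([[c, 0.0, -s], [0.0, 1.0, 0.0], [s, 0.0, c]])
    if axis == "Z":
        return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    raise ValueError(f"unknown axis {axis!r}")


def horizontal_angle(azimuth_deg: float, elevation_deg: float) -> float:
    """Horizontal angle alpha = asin(sin(theta) cos(phi)), in degrees."""
    s = np.sin(np.deg2rad(azimuth_deg)) * np.cos(np.deg2rad(elevation_deg))
    return float(np.rad2deg(np.arcsin(np.clip(s, -1.0, 1.0))))


def azimuth_from_horizontal(horizontal_deg: float, elevation_deg: float) -> float:
    """Invert :func:`horizontal_angle` for |azimuth| < 90 deg."""
    c = np.cos(np.deg2rad(elevation_deg))
    if c <= 0.0:
        raise ValueError("elevation must lie strictly inside (-90, 90) deg")
    s = np.sin(np.deg2rad(horizontal_deg)) / c
    if np.abs(s) > 1.0 + 1e-12:
        raise ValueError(
            f"no azimuth reaches horizontal angle {horizontal_deg} at "
            f"elevation {elevation_deg}"
        )
    return float(np.rad2deg(np.arcsin(np.clip(s, -1.0, 1.0))))


def direction_from_angles(azimuth_deg: float, elevation_deg: float) -> np.ndarray:
    """Unit vector (X forward, Y left, Z up) from azimuth/elevation."""
    az, el = np.deg2rad(azimuth_deg), np.deg2rad(elevation_deg)
    return np.array(
        [np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)]
    )


def direction_from_horizontal(horizontal_deg: float, elevation_deg: float) -> np.ndarray:
    """Unit vector in the frontal hemisphere from (horizontal, elevation)."""
    y = np.sin(np.deg2rad(horizontal_deg))
    z = np.sin(np.deg2rad(elevation_deg))
    x2 = 1.0 - y * y - z * z
    if x2 < -1e-12:
        raise ValueError(
            f"({horizontal_deg}, {elevation_deg}) deg lies outside the "
            "frontal hemisphere"
        )
    return np.array([np.sqrt(max(x2, 0.0)), y, z])


def angles_from_direction(v: np.ndarray) -> DirectionAngles:
    """Azimuth/elevation (deg) of a direction vector."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero direction vector")
    v = v / n
    az = np.rad2deg(np.arctan2(v[1], v[0]))
    el = np.rad2deg(np.arcsin(np.clip(v[2], -1.0, 1.0)))
    return DirectionAngles(float(az), float(el))


def update_head_rotation(
    R_prev: np.ndarray, dyaw_deg: float, dpitch_deg: float
) -> tuple[np.ndarray, np.ndarray]:
    """Apply incremental yaw/pitch commands to the accumulated pose.

    ``R_prev`` is the accumulated body-to-head matrix.  The update is
    ``R = P_Y(dpitch) P_Z(dyaw) R_prev`` with passive increments
    (transposed active rotations), after which the result is projected
    back onto SO(3) to stop floating-point drift over long episodes.

    Returns
    -------
    (R, head_direction)
        Updated body-to-head matrix and the head direction in body
        coordinates, ``R^-1 (1, 0, 0)``.
    """
    R_prev = _check_rotation(R_prev)
    R = (
        elementary_rotation("Y", dpitch_deg).T
        @ elementary_rotation("Z", dyaw_deg).T
        @ R_prev
    )
    R = _orthonormalize(R)
    head = R.T @ np.array([1.0, 0.0, 0.0])
    return R, head


def listing_torsion(yaw_deg: float, pitch_deg: float) -> float:
    """Mean torsion (deg) assigned by Listing's law to a head direction.

    Half the yaw-pitch product, evaluated in radians (the small-angle
    form of Listing's law) and converted back to degrees.
    """
    if not (np.isfinite(yaw_deg) and np.isfinite(pitch_deg)):
        raise ValueError("angles must be finite")
    return float(
        np.rad2deg(np.deg2rad(yaw_deg) * np.deg2rad(pitch_deg) / 2.0)
    )


def head_pose_with_roll(
    yaw_deg: float, pitch_deg: float, roll_deg: float
) -> tuple[FickAngles, np.ndarray]:
    """Full Fick pose for a head direction plus an active roll sample.

    The torsion is the Listing torsion of (yaw, pitch) perturbed by the
    roll sample.  Returns the Fick angles and the head-to-body matrix
    ``R_HB = R_Z(yaw) R_Y(pitch) R_X(torsion)``.
    """
    torsion = listing_torsion(yaw_deg, pitch_deg) + float(roll_deg)
    fick = FickAngles(float(yaw_deg), float(pitch_deg), torsion)
    R = (
        elementary_rotation("Z", fick.yaw)
        @ elementary_rotation("Y", fick.pitch)
        @ elementary_rotation("X", fick.torsion)
    )
    return fick, R


def fick_decompose(R: np.ndarray) -> FickAngles:
    """Recover Fick angles from a head-to-body rotation matrix.

    Raises
    ------
    GimbalLockError
        If |pitch| is within tolerance of 90 deg, where yaw and torsion
        are not separately defined.
    """
    R = _check_rotation(R)
    sp = np.clip(R[2, 0], -1.0, 1.0)
    pitch = np.rad2deg(np.arcsin(sp))
    if 90.0 - abs(pitch) < _GIMBAL_TOL_DEG:
        raise GimbalLockError("pitch at +/-90 deg: Fick angles degenerate")
    yaw = np.rad2deg(np.arctan2(R[1, 0], R[0, 0]))
    M = (
        elementary_rotation("Y", pitch).T
        @ elementary_rotation("Z", yaw).T
        @ R
    )
    torsion = np.rad2deg(np.arctan2(M[2, 1], M[1, 1]))
    return FickAngles(float(yaw), float(pitch), float(torsion))


def target_in_head_coords(
    R_BH: np.ndarray, s_B: np.ndarray
) -> tuple[np.ndarray, DirectionAngles]:
    """Transform the sound-source direction into head-centred coordinates.

    Parameters
    ----------
    R_BH : (3, 3) array
        Body-to-head rotation (transpose of the head pose ``R_HB``).
    s_B : (3,) array
        Unit direction to the source in body coordinates.

    Returns
    -------
    (s_H, angles)
        Direction in head coordinates and its azimuth/elevation; the pair
        (horizontal, elevation) is (0, 0) iff the head points at the
        target.
    """
    R_BH = _check_rotation(R_BH)
    s_B = np.asarray(s_B, dtype=float)
    n = np.linalg.norm(s_B)
    if n < 1e-12:
        raise ValueError("zero target direction")
    s_H = R_BH @ (s_B / n)
    return s_H, angles_from_direction(s_H)


# ---------------------------------------------------------------------------
# Marker-based pose estimation (motion-capture triplets)
# ---------------------------------------------------------------------------

#: Reference marker layout (mm): left pinna tip, right pinna tip, head.
MARKER_TEMPLATE = np.array(
    [[-5.0, 8.0, 6.0], [-5.0, -8.0, 6.0], [4.0, 0.0, 0.0]]
)


def _marker_frame(markers: np.ndarray) -> np.ndarray:
    """Orthonormal frame [Vx Vy Vz] from a (left, right, head) triplet.

    Vz runs from the head marker through the orthocenter of the marker
    triangle (hence perpendicular to the inter-pinna line, which makes the
    estimate insensitive to symmetric pinna raising/lowering), Vy is the
    normal of the marker plane, and Vx = Vy x Vz.
    """
    markers = np.asarray(markers, dtype=float)
    if markers.shape != (3, 3):
        raise ValueError("markers must be a 3x3 array (left, right, head)")
    L, Rm, H = markers
    n = np.cross(L - H, Rm - H)
    nn = np.linalg.norm(n)
    scale = max(np.linalg.norm(L - H), np.linalg.norm(Rm - H), 1e-12)
    if nn < 1e-9 * scale * scale:
        raise CollinearMarkersError("markers are (nearly) collinear")
    Vy = n / nn
    # altitude from the head marker: in-plane, perpendicular to L-R
    u = np.cross(Vy, Rm - L)
    u = u / np.linalg.norm(u)
    denom = float(u @ (H - Rm))
    if abs(denom) < 1e-12:
        raise CollinearMarkersError("degenerate triangle (right angle at head)")
    t = float((L - H) @ (H - Rm)) / denom
    ortho = H + t * u
    Vz = ortho - H
    vn = np.linalg.norm(Vz)
    if vn < 1e-12:
        raise CollinearMarkersError("orthocenter coincides with head marker")
    Vz = Vz / vn
    Vx = np.cross(Vy, Vz)
    return np.column_stack([Vx, Vy, Vz])


_TEMPLATE_FRAME = _marker_frame(MARKER_TEMPLATE)


def estimate_pose_from_markers(markers: np.ndarray) -> FickAngles:
    """Fick head pose from a (left pinna, right pinna, head) marker triplet.

    The pose is the rotation carrying the reference marker layout
    (:data:`MARKER_TEMPLATE`) onto the observed one; translations cancel.
    """
    M = _marker_frame(markers)
    R = _orthonormalize(M @ _TEMPLATE_FRAME.T)
    return fick_decompose(R)


def read_marker_csv(path) -> dict[int, np.ndarray]:
    """Read marker triplets from CSV (columns frame, marker, x, y, z; mm).

    Marker names must be ``left``, ``right``, ``head``.  Returns a map
    frame -> 3x3 array ordered (left, right, head).
    """
    df = pd.read_csv(path)
    required = {"frame", "marker", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"marker CSV needs columns {sorted(required)}")
    out: dict[int, np.ndarray] = {}
    for frame, grp in df.groupby("frame"):
        rows = grp.set_index("marker")
        try:
            trip = np.array(
                [rows.loc[m, ["x", "y", "z"]].to_numpy(dtype=float)
                 for m in ("left", "right", "head")]
            )
        except KeyError as exc:
            raise ValueError(f"frame {frame} is missing marker {exc}") from exc
        out[int(frame)] = trip
    return out


def poses_to_csv(poses: dict[int, FickAngles], path) -> None:
    """Write per-frame Fick poses (deg) as CSV (frame, yaw, pitch, torsion)."""
    df = pd.DataFrame(
        [
            {"frame": f, "yaw": p.yaw, "pitch": p.pitch, "torsion": p.torsion}
            for f, p in sorted(poses.items())
        ]
    )
    df.to_csv(path, index=False)
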