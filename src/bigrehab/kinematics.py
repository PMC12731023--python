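"""Screw-theory and vector-loop kinematics of the 3-PUU-R ankle mechanism.

The trainer is a hybrid mechanism: three identical Prismatic-Universal-
Universal branches connect a fixed platform to a moving platform (two
rotational plus one translational degree of freedom), and a serial revolute
joint on the moving platform carries the pedal, for four degrees of freedom
overall.

This module provides

* the modified Kutzbach-Gruebler mobility count and the branch joint census,
* branch motion screws and their reciprocal (constraint) wrench system in
  Pluecker ray coordinates (axis; moment),
* inverse kinematics of the vector loop  P + R f_i = n_i + m_i M_i + e_i E_i,
* the velocity Jacobians J_x (platform twist -> weighted stroke rates),
  J_m = diag(M_i . E_i) and J_p = J_m^{-1} J_x,
* the platform <-> pedal twist and acceleration transfer across the
  revolute offset r, and
* range-of-motion checking of labelled ankle-angle trajectories.

Orientations are rotation matrices internally; configuration files accept
XYZ Euler angles in degrees, matching clinical angle conventions.  Platform
attachment offsets are stored in the moving frame and rotated to the fixed
frame at the current pose wherever they enter a Jacobian.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import null_space
from scipy.spatial.transform import Rotation

from .errors import (
    SingularityError,
    StrokeLimitError,
    UnreachablePoseError,
    ValidationError,
)

__all__ = [
    "JointCensus",
    "MechanismGeometry",
    "PlatformPose",
    "KinematicState",
    "ScrewSystem",
    "ROMLimits",
    "mobility",
    "joint_census_puu",
    "branch_motion_screws",
    "klein_product",
    "reciprocal_screws",
    "inverse_kinematics",
    "jacobians",
    "stroke_rates",
    "pedal_twist",
    "platform_twist_from_pedal",
    "accelerations",
    "pedal_acceleration",
    "check_rom",
    "rom_limits",
    "default_geometry",
]


def _skew(v: np.ndarray) -> np.ndarray:
    x, y, z = v
    return np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])


# -- mobility --------------------------------------------------------------


@dataclass(frozen=True)
class JointCensus:
    """Link/joint counts feeding the Kutzbach-Gruebler formula."""

    n_links: int          # total links, frame included
    f_per_joint: tuple[int, ...]
    overconstraints: int = 0
    order: int = 6        # 3 planar, 6 spatial

    def __post_init__(self):
        if self.order not in (3, 6):
            raise ValidationError("mechanism order must be 3 or 6")
        if any(f not in (1, 2, 3) for f in self.f_per_joint):
            raise ValidationError("joint freedoms must each be 1, 2 or 3")

    @property
    def n_joints(self) -> int:
        return len(self.f_per_joint)

    @property
    def sum_f(self) -> int:
        return sum(self.f_per_joint)


def mobility(census: JointCensus) -> int:
    """M = d (n - g - 1) + sum f_i + v."""
    return (census.order * (census.n_links - census.n_joints - 1)
            + census.sum_f + census.overconstraints)


def joint_census_puu() -> JointCensus:
    """Census of the 3-PUU parallel part: 8 links, 3 prismatic joints and
    6 Hooke joints (9 pairs, sum f = 3*1 + 6*2 = 15), no overconstraints."""
    return JointCensus(n_links=8, f_per_joint=(1, 1, 1, 2, 2, 2, 2, 2, 2),
                       overconstraints=0, order=6)


# -- screws ----------------------------------------------------------------


@dataclass
class ScrewSystem:
    """Rows are 6-vectors in Pluecker ray coordinates (axis; moment)."""

    screws: np.ndarray

    def __post_init__(self):
        self.screws = np.atleast_2d(np.asarray(self.screws, dtype=float))
        if self.screws.shape[-1] != 6:
            raise ValidationError("screws must be 6-vectors")
        if not np.isfinite(self.screws).all():
            raise ValidationError("screws must be finite")

    @property
    def dimension(self) -> int:
        return int(np.linalg.matrix_rank(self.screws)) if self.screws.size else 0

    def __len__(self) -> int:
        return self.screws.shape[0]


def branch_motion_screws(e: float, f: float, m: float, n: float) -> ScrewSystem:
    """The five motion screws of one PUU branch in its branch frame.

    The parameters depend solely on the positions of the revolute axes
    making up the two Hooke joints; the structural result (a single
    constraint couple about the branch x-axis) holds for generic values.
    """
    return ScrewSystem(np.array([
        [0, 0, 0, 0, 0, 1],
        [0, 0, 1, 0, 0, 0],
        [1, 0, 0, 0, e, 0],
        [1, 0, 0, 0, 0, f],
        [0, m, n, 0, 0, 0],
    ], dtype=float))


def klein_product(s: np.ndarray, w: np.ndarray) -> float:
    """Reciprocal (Klein) product of two screws in ray coordinates."""
    s, w = np.asarray(s, dtype=float), np.asarray(w, dtype=float)
    return float(s[:3] @ w[3:] + s[3:] @ w[:3])


def reciprocal_screws(system: ScrewSystem) -> ScrewSystem:
    """Basis of all wrenches reciprocal to every screw of ``system``.

    A wrench w is reciprocal to a twist s when their Klein product
    vanishes, i.e. when the coordinate-interchanged twist matrix
    annihilates w; the basis is the SVD null space of that matrix.  The
    reciprocal dimension is 6 minus the system rank.
    """
    if len(system) == 0:
        raise ValidationError("screw system is empty")
    interchanged = np.hstack([system.screws[:, 3:], system.screws[:, :3]])
    basis = null_space(interchanged)
    return ScrewSystem(basis.T if basis.size else np.empty((0, 6)))


# -- geometry and poses ----------------------------------------------------


@dataclass
class MechanismGeometry:
    """Branch attachment layout (metres).

    ``base_points`` n_i are fixed-platform attachments, ``platform_points``
    f_i moving-platform attachments in the moving frame, ``directions`` M_i
    unit prismatic axes, ``rod_lengths`` e_i the u_i b_i rod lengths,
    ``stroke_limits`` per-branch actuator ranges, and ``pedal_offset`` r
    the revolute-joint vector from moving-platform centre to pedal.
    """

    base_points: np.ndarray
    platform_points: np.ndarray
    directions: np.ndarray
    rod_lengths: np.ndarray
    stroke_limits: np.ndarray
    pedal_offset: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.base_points = np.asarray(self.base_points, dtype=float)
        self.platform_points = np.asarray(self.platform_points, dtype=float)
        self.directions = np.asarray(self.directions, dtype=float)
        self.rod_lengths = np.asarray(self.rod_lengths, dtype=float)
        self.stroke_limits = np.asarray(self.stroke_limits, dtype=float)
        self.pedal_offset = np.asarray(self.pedal_offset, dtype=float)
        for name, arr, shape in (
            ("base_points", self.base_points, (3, 3)),
            ("platform_points", self.platform_points, (3, 3)),
            ("directions", self.directions, (3, 3)),
            ("rod_lengths", self.rod_lengths, (3,)),
            ("stroke_limits", self.stroke_limits, (3, 2)),
            ("pedal_offset", self.pedal_offset, (3,)),
        ):
            if arr.shape != shape:
                raise ValidationError(f"{name}: expected shape {shape}, got {arr.shape}")
        norms = np.linalg.norm(self.directions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValidationError("prismatic directions must be unit vectors")
        if np.any(self.rod_lengths <= 0):
            raise ValidationError("rod lengths must be positive")

    @classmethod
    def from_config(cls, config: Mapping) -> "MechanismGeometry":
        try:
            return cls(
                base_points=config["base_points"],
                platform_points=config["platform_points"],
                directions=config["directions"],
                rod_lengths=config["rod_lengths"],
                stroke_limits=config["stroke_limits"],
                pedal_offset=config.get("pedal_offset", (0.0, 0.0, 0.0)),
            )
        except KeyError as exc:
            raise ValidationError(f"geometry config missing key {exc}") from exc


def default_geometry() -> MechanismGeometry:
    text = resources.files("bigrehab.data").joinpath("geometry_default.json").read_text()
    return MechanismGeometry.from_config(json.loads(text))


@dataclass
class PlatformPose:
    """Moving-platform position (m) and orientation (proper rotation)."""

    position: np.ndarray
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.rotation = np.asarray(self.rotation, dtype=float)
        if self.position.shape != (3,):
            raise ValidationError("position must be a 3-vector")
        if self.rotation.shape != (3, 3):
            raise ValidationError("rotation must be a 3x3 matrix")
        if (abs(np.linalg.det(self.rotation) - 1.0) > 1e-9
                or not np.allclose(self.rotation.T @ self.rotation, np.eye(3),
                                   atol=1e-9)):
            raise ValidationError("rotation must be proper orthogonal (det +1)")

    @classmethod
    def from_euler(cls, position: Sequence[float],
                   euler_xyz_deg: Sequence[float]) -> "PlatformPose":
        rot = Rotation.from_euler("xyz", euler_xyz_deg, degrees=True).as_matrix()
        return cls(np.asarray(position, dtype=float), rot)


@dataclass
class KinematicState:
    """IK solution (strokes and unit rod directions) plus optional rates."""

    strokes: np.ndarray
    rod_dirs: np.ndarray
    stroke_rates: np.ndarray | None = None
    rod_angular_velocities: np.ndarray | None = None

    def __post_init__(self):
        norms = np.linalg.norm(self.rod_dirs, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValidationError("rod directions must be unit vectors")


# -- inverse kinematics ----------------------------------------------------


def inverse_kinematics(pose: PlatformPose, geom: MechanismGeometry,
                       previous_strokes: Sequence[float] | None = None,
                       ) -> KinematicState:
    """Solve the branch vector loops for strokes m_i and rod directions E_i.

    Writing c_i = P + R f_i - n_i, the loop requires |c_i - m_i M_i| = e_i,
    a quadratic in m_i.  Root choice: a root inside the stroke limits; when
    both qualify, the one nearer the previous stroke (trajectory
    continuity) or else the smaller.  No real root raises
    :class:`UnreachablePoseError`; both roots out of range raise
    :class:`StrokeLimitError`.
    """
    strokes = np.empty(3)
    rods = np.empty((3, 3))
    for i in range(3):
        c = pose.position + pose.rotation @ geom.platform_points[i] - geom.base_points[i]
        M = geom.directions[i]
        b = c @ M
        disc = b * b - c @ c + geom.rod_lengths[i] ** 2
        if disc < 0:
            raise UnreachablePoseError(
                f"branch {i}: no real stroke (discriminant {disc:.3g})"
            )
        roots = np.array([b - np.sqrt(disc), b + np.sqrt(disc)])
        lo, hi = geom.stroke_limits[i]
        valid = roots[(roots >= lo - 1e-12) & (roots <= hi + 1e-12)]
        if valid.size == 0:
            raise StrokeLimitError(
                f"branch {i}: roots {roots} outside stroke limits [{lo}, {hi}]"
            )
        if valid.size == 2 and previous_strokes is not None:
            m = valid[np.argmin(np.abs(valid - previous_strokes[i]))]
        else:
            m = valid.min()
        strokes[i] = m
        rods[i] = (c - m * M) / geom.rod_lengths[i]
    return KinematicState(strokes=strokes, rod_dirs=rods)


def loop_residuals(pose: PlatformPose, geom: MechanismGeometry,
                   state: KinematicState) -> np.ndarray:
    """Norm of the closed-loop residual per branch (should be ~0)."""
    res = np.empty(3)
    for i in range(3):
        lhs = pose.position + pose.rotation @ geom.platform_points[i]
        rhs = (geom.base_points[i] + state.strokes[i] * geom.directions[i]
               + geom.rod_lengths[i] * state.rod_dirs[i])
        res[i] = np.linalg.norm(lhs - rhs)
    return res


# -- Jacobians and velocity ------------------------------------------------


def jacobians(pose: PlatformPose, geom: MechanismGeometry,
              state: KinematicState) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (J_x, J_m, J_p) at the given configuration.

    Row i of J_x is [E_i^T, -E_i^T skew(f_i)] with f_i rotated to the fixed
    frame at the current pose; J_m = diag(M_i . E_i); J_p = J_m^{-1} J_x
    maps the platform twist [V_p; w_p] to stroke rates.  A vanishing
    M_i . E_i is a force-transmission singularity.
    """
    Jx = np.empty((3, 6))
    diag = np.empty(3)
    for i in range(3):
        E = state.rod_dirs[i]
        f_fixed = pose.rotation @ geom.platform_points[i]
        Jx[i, :3] = E
        Jx[i, 3:] = -E @ _skew(f_fixed)
        diag[i] = geom.directions[i] @ E
        if abs(diag[i]) < 1e-8:
            raise SingularityError(
                f"branch {i}: rod orthogonal to drive axis (M.E = {diag[i]:.2e})"
            )
    Jm = np.diag(diag)
    Jp = Jx / diag[:, None]
    return Jx, Jm, Jp


def stroke_rates(pose: PlatformPose, geom: MechanismGeometry,
                 state: KinematicState, v_p: np.ndarray, w_p: np.ndarray,
                 ) -> np.ndarray:
    """Prismatic rates for a platform twist: m_dot = J_p [V_p; w_p]."""
    _, _, Jp = jacobians(pose, geom, state)
    return Jp @ np.concatenate([np.asarray(v_p, float), np.asarray(w_p, float)])


def rod_angular_velocities(pose: PlatformPose, geom: MechanismGeometry,
                           state: KinematicState, v_p: np.ndarray,
                           w_p: np.ndarray) -> np.ndarray:
    """Angular velocity of each rod, assuming no spin about the rod axis
    (the spin component of a UU rod is unobservable)."""
    v_p, w_p = np.asarray(v_p, float), np.asarray(w_p, float)
    mdot = stroke_rates(pose, geom, state, v_p, w_p)
    out = np.empty((3, 3))
    for i in range(3):
        f_fixed = pose.rotation @ geom.platform_points[i]
        u = v_p + np.cross(w_p, f_fixed)          # attachment-point velocity
        rod_rate = u - mdot[i] * geom.directions[i]
        out[i] = np.cross(state.rod_dirs[i], rod_rate) / geom.rod_lengths[i]
    return out


def pedal_twist(v_p: np.ndarray, w_p: np.ndarray, r: np.ndarray,
                ) -> tuple[np.ndarray, np.ndarray]:
    """Twist of the pedal point: V_o = V_p + w_p x r, w_o = w_p."""
    v_p, w_p, r = (np.asarray(a, float) for a in (v_p, w_p, r))
    return v_p + np.cross(w_p, r), w_p.copy()


def platform_twist_from_pedal(v_o: np.ndarray, w_o: np.ndarray, r: np.ndarray,
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Inverse map via the 6x6 block [[I, skew(r)], [0, I]]."""
    v_o, w_o, r = (np.asarray(a, float) for a in (v_o, w_o, r))
    block = np.block([[np.eye(3), _skew(r)], [np.zeros((3, 3)), np.eye(3)]])
    twist = block @ np.concatenate([v_o, w_o])
    return twist[:3], twist[3:]


# -- accelerations ---------------------------------------------------------


def accelerations(pose: PlatformPose, geom: MechanismGeometry,
                  state: KinematicState, v_p: np.ndarray, w_p: np.ndarray,
                  a_p: np.ndarray, eps_p: np.ndarray) -> np.ndarray:
    """Prismatic accelerations for a platform twist and acceleration.

    Differentiates m_dot_i = (u_i . E_i) / (M_i . E_i) with
    u_i = V_p + w_p x f_i (fixed-frame attachment velocity),
    u_dot_i = a_p + eps_p x f_i + w_p x (w_p x f_i), and
    E_dot_i = w_i x E_i from the rod angular velocity.
    """
    v_p, w_p, a_p, eps_p = (np.asarray(a, float) for a in (v_p, w_p, a_p, eps_p))
    mdot = stroke_rates(pose, geom, state, v_p, w_p)
    w_rods = rod_angular_velocities(pose, geom, state, v_p, w_p)
    out = np.empty(3)
    for i in range(3):
        E, M = state.rod_dirs[i], geom.directions[i]
        f_fixed = pose.rotation @ geom.platform_points[i]
        u = v_p + np.cross(w_p, f_fixed)
        udot = a_p + np.cross(eps_p, f_fixed) + np.cross(w_p, np.cross(w_p, f_fixed))
        Edot = np.cross(w_rods[i], E)
        D = M @ E
        if abs(D) < 1e-8:
            raise SingularityError(f"branch {i}: singular configuration")
        out[i] = ((udot @ E + u @ Edot) * D - (u @ E) * (M @ Edot)) / (D * D)
    return out


def pedal_acceleration(a_p: np.ndarray, eps_p: np.ndarray, w_p: np.ndarray,
                       r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pedal accelerations (xi_c, eps_c) from platform accelerations:
    xi_c = a_p + eps_p x r + w_p x (w_p x r), eps_c = eps_p."""
    a_p, eps_p, w_p, r = (np.asarray(a, float) for a in (a_p, eps_p, w_p, r))
    xi = a_p + np.cross(eps_p, r) + np.cross(w_p, np.cross(w_p, r))
    return xi, eps_p.copy()


# -- range of motion -------------------------------------------------------

MOTIONS = ("plantarflexion", "dorsiflexion", "inversion", "eversion",
           "internal_rotation", "external_rotation")


@dataclass
class ROMLimits:
    """Maximum angles (deg) per motion, physiological and gait variants."""

    physiological: dict[str, float]
    gait: dict[str, float]

    def __post_init__(self):
        for variant in (self.physiological, self.gait):
            for motion, angle in variant.items():
                if motion not in MOTIONS:
                    raise ValidationError(f"unknown motion label {motion!r}")
                if angle < 0:
                    raise ValidationError(f"{motion}: limit must be >= 0")
        for motion in self.gait:
            if motion in self.physiological and (
                    self.gait[motion] > self.physiological[motion]):
                raise ValidationError(
                    f"{motion}: gait range exceeds physiological range"
                )

    def limit(self, motion: str, variant: str) -> float:
        table = {"physiological": self.physiological, "gait": self.gait}
        if variant not in table:
            raise ValidationError(f"unknown ROM variant {variant!r}")
        if motion not in table[variant]:
            raise ValidationError(f"unknown motion label {motion!r}")
        return table[variant][motion]


def rom_limits(preset: str = "physiological") -> ROMLimits:
    """Packaged limits; ``preset`` selects the physiological variant
    ('physiological' from the tabulated limits, 'physiological_extended'
    from the device-design prose, which disagree on external rotation)."""
    text = resources.files("bigrehab.data").joinpath("rom_limits.json").read_text()
    presets = json.loads(text)["presets"]
    if preset not in ("physiological", "physiological_extended"):
        raise ValidationError(f"unknown ROM preset {preset!r}")
    return ROMLimits(physiological=presets[preset], gait=presets["gait"])


def check_rom(trajectory: pd.DataFrame, limits: ROMLimits,
              variant: str = "physiological") -> dict:
    """Check a labelled angle trajectory against ROM limits.

    ``trajectory`` needs columns ``motion`` and ``angle_deg``.  Returns a
    report with per-motion violation counts and the offending sample
    indices.
    """
    for col in ("motion", "angle_deg"):
        if col not in trajectory.columns:
            raise ValidationError(f"trajectory is missing column {col!r}")
    bad = set(trajectory["motion"]) - set(MOTIONS)
    if bad:
        raise ValidationError(f"unknown motion label(s) {sorted(bad)}")
    per_motion: dict[str, dict] = {}
    total = 0
    for motion, group in trajectory.groupby("motion", sort=True):
        lim = limits.limit(motion, variant)
        angles = group["angle_deg"].to_numpy(dtype=float)
        mask = angles > lim
        per_motion[motion] = {
            "limit_deg": lim,
            "n_samples": int(len(angles)),
            "n_violations": int(mask.sum()),
            "violation_indices": group.index[mask].tolist(),
        }
        total += int(mask.sum())
    return {
        "variant": variant,
        "n_samples": int(len(trajectory)),
        "n_violations": total,
        "per_motion": per_motion,
    }
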