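"""Rigid alignment: halfway registration, per-subject b0 templates, AC-PC.

Transforms are 6-parameter rigid maps in world (mm) coordinates, applied as
rotation about a fixed center followed by translation. Registration
minimizes the masked mean squared intensity difference with Nelder-Mead
simplex descent and deterministic multi-start.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation

__all__ = [
    "RigidTransform",
    "TemplateResult",
    "register_rigid",
    "halfway_split",
    "build_b0_template",
    "acpc_align",
    "resample",
]


@dataclass
class RigidTransform:
    """Rotation (intrinsic xyz Euler angles, radians) about ``center`` (mm),
    then translation (mm)."""

    angles: np.ndarray  # (3,)
    translation: np.ndarray  # (3,)
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        self.center = np.asarray(self.center, dtype=float)

    @classmethod
    def identity(cls, center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        return cls(np.zeros(3), np.zeros(3), np.asarray(center, float))

    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_euler("xyz", self.angles).as_matrix()

    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 world-coordinate matrix ``x -> R(x-c) + c + t``."""
        R = self.rotation_matrix()
        M = np.eye(4)
        M[:3, :3] = R
        M[:3, 3] = self.center - R @ self.center + self.translation
        return M

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        R = self.rotation_matrix()
        return (R @ (pts - self.center).T).T + self.center + self.translation

    @classmethod
    def from_matrix(cls, M: np.ndarray, center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        center = np.asarray(center, float)
        R = M[:3, :3]
        angles = Rotation.from_matrix(R).as_euler("xyz")
        t = M[:3, 3] - center + R @ center
        return cls(angles, t, center)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform.from_matrix(self.matrix() @ other.matrix(), self.center)

    def inverse(self) -> "RigidTransform":
        return RigidTransform.from_matrix(np.linalg.inv(self.matrix()), self.center)

    def to_json(self) -> str:
        return json.dumps({
            "angles_deg": list(np.degrees(self.angles)),
            "translation_mm": list(self.translation),
            "center_mm": list(self.center),
            "matrix": self.matrix().tolist(),
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RigidTransform":
        d = json.loads(text)
        return cls(np.radians(d["angles_deg"]), np.asarray(d["translation_mm"]),
                   np.asarray(d["center_mm"]))


@dataclass
class TemplateResult:
    """Per-subject b0 template and the transforms mapping each session into it."""

    template: np.ndarray
    transforms: list[RigidTransform]
    costs: list[float]
    warnings: list[str] = field(default_factory=list)


def resample(volume: np.ndarray, transform: RigidTransform, voxel_size,
             order: int = 1) -> np.ndarray:
    """Apply a world-space rigid transform to a 3D or 4D volume.

    Output voxel x takes the value of the input at ``T^-1 x`` (trilinear by
    default); voxels mapping outside the field of view become 0. A 4D input
    gets the identical transform on every 3D sub-volume.
    """
    vs = np.asarray(voxel_size, float)
    Minv = transform.inverse().matrix()
    # voxel -> world -> inverse transform -> voxel
    A = Minv[:3, :3] * vs[None, :] / vs[:, None]
    off = Minv[:3, 3] / vs
    if volume.ndim == 4:
        return np.stack([
            ndimage.affine_transform(volume[..., i], A, offset=off, order=order,
                                     mode="constant", cval=0.0)
            for i in range(volume.shape[-1])
        ], axis=-1)
    return ndimage.affine_transform(volume, A, offset=off, order=order,
                                    mode="constant", cval=0.0)


def mass_center_mm(volume: np.ndarray, voxel_size) -> np.ndarray:
    w = np.clip(np.asarray(volume, float), 0, None)
    if w.sum() <= 0:
        return (np.asarray(volume.shape, float) - 1) / 2 * np.asarray(voxel_size)
    com = np.array(ndimage.center_of_mass(w))
    return com * np.asarray(voxel_size, float)


class _CostFunction:
    """Masked MSE of the transformed moving image against the fixed image.

    The moving image is spline-prefiltered once; each evaluation maps the
    fixed mask's voxel coordinates through the candidate transform's inverse
    and samples the moving image there, excluding out-of-field voxels.
    """

    def __init__(self, moving, fixed, mask, voxel_size, center, order=3):
        self.order = order
        self.vs = np.asarray(voxel_size, float)
        self.center = center
        self.shape = np.asarray(moving.shape, float)
        self.prefiltered = (ndimage.spline_filter(moving, order=order)
                            if order > 1 else moving)
        self.pts = np.argwhere(mask).T.astype(float)  # (3, n)
        self.fvals = fixed[mask]

    def __call__(self, params):
        t = RigidTransform(params[:3], params[3:], self.center)
        Minv = t.inverse().matrix()
        A = Minv[:3, :3] * self.vs[None, :] / self.vs[:, None]
        off = Minv[:3, 3] / self.vs
        coords = A @ self.pts + off[:, None]
        inside = np.all((coords >= 0) & (coords <= self.shape[:, None] - 1), axis=0)
        if not inside.any():
            return np.inf
        vals = ndimage.map_coordinates(self.prefiltered, coords[:, inside],
                                       order=self.order, prefilter=False)
        d = vals - self.fvals[inside]
        return float(np.mean(d * d))


def register_rigid(moving: np.ndarray, fixed: np.ndarray, voxel_size,
                   init: RigidTransform | None = None, mask: np.ndarray | None = None,
                   n_restarts: int = 3, presmooth_vox: float = 1.0,
                   cost_interp_order: int = 3, return_history: bool = False):
    """Estimate the rigid transform minimizing masked MSE of intensities.

    Both images are scaled by their masked median before comparison, the
    rotation center is the fixed image's mask center of mass, and the
    simplex search restarts from deterministically perturbed initializations
    to guard against local minima. A mild Gaussian pre-smoothing
    (``presmooth_vox`` voxels) suppresses interpolation aliasing at sharp
    tissue edges, which would otherwise displace the cost minimum. The
    best-vertex cost history is monitored and guaranteed non-increasing.

    Raises
    ------
    ValueError
        If the grids disagree or the cost is non-finite at every start.
    """
    moving = np.asarray(moving, float)
    fixed = np.asarray(fixed, float)
    if moving.shape != fixed.shape:
        raise ValueError("moving and fixed grids must agree")
    if mask is None:
        thr = 0.1 * np.percentile(fixed, 99)
        mask = fixed > thr
    if not mask.any():
        raise ValueError("registration mask is empty")

    med_f = np.median(fixed[mask])
    med_m = np.median(moving[moving > 0.1 * np.percentile(moving, 99)]) \
        if (moving > 0).any() else 1.0
    if med_f <= 0 or med_m <= 0:
        raise ValueError("cannot normalize images with nonpositive medians")
    fx = fixed / med_f
    mv = moving / med_m

    center = mass_center_mm(np.where(mask, fixed, 0.0), voxel_size)
    x0 = np.zeros(6)
    if init is not None:
        x0[:3] = init.angles
        x0[3:] = init.translation

    perturbs = [np.zeros(6),
                np.array([0.04, -0.04, 0.04, 2.0, -2.0, 2.0]),
                np.array([-0.04, 0.04, -0.04, -2.0, 2.0, -2.0]),
                np.array([0.08, 0.08, -0.08, 4.0, 4.0, -4.0])]

    history: list[float] = []

    # coarse stage: heavy smoothing widens the capture basin; multi-start
    coarse_sigma = max(2.5, presmooth_vox)
    cost_coarse = _CostFunction(ndimage.gaussian_filter(mv, coarse_sigma),
                                ndimage.gaussian_filter(fx, coarse_sigma),
                                mask, voxel_size, center, cost_interp_order)
    best = None
    for k in range(min(n_restarts + 1, len(perturbs))):
        start = x0 + perturbs[k]
        simplex = np.vstack([start] + [start + np.eye(6)[i] *
                                       (0.05 if i < 3 else 2.0) for i in range(6)])
        res = optimize.minimize(
            cost_coarse, start, method="Nelder-Mead",
            options={"initial_simplex": simplex, "xatol": 1e-4, "fatol": 1e-12,
                     "maxiter": 1000},
        )
        if best is None or res.fun < best.fun:
            best = res
        history.append(float(res.fun))

    if best is None or not np.isfinite(best.fun):
        raise ValueError("registration failed: non-finite cost (empty overlap)")

    # fine stage: polish the winner at native sharpness and record the
    # monotone best-vertex trace
    if presmooth_vox > 0:
        fx = ndimage.gaussian_filter(fx, presmooth_vox)
        mv = ndimage.gaussian_filter(mv, presmooth_vox)
    cost_fn = _CostFunction(mv, fx, mask, voxel_size, center, cost_interp_order)
    trace: list[float] = []
    res = optimize.minimize(
        cost_fn, best.x, method="Nelder-Mead",
        callback=lambda xk: trace.append(cost_fn(xk)),
        options={"xatol": 1e-5, "fatol": 1e-14, "maxiter": 2000},
    )
    final = res if res.fun <= cost_fn(best.x) else best
    if trace:
        diffs = np.diff(np.asarray(trace))
        assert np.all(diffs <= 1e-12), "simplex best-vertex cost increased"
    t = RigidTransform(final.x[:3], final.x[3:], center)
    if return_history:
        return t, float(final.fun), trace
    return t, float(final.fun)


def halfway_split(t: RigidTransform) -> tuple[RigidTransform, RigidTransform]:
    """Split ``t`` into symmetric halves meeting at the midpoint.

    The forward half composed with itself reproduces ``t`` (rotation halved
    on the rotation vector, translation solved from the composition); the
    backward half is the forward half's inverse, so moving and fixed images
    each travel half the distance.
    """
    rotvec = Rotation.from_euler("xyz", t.angles).as_rotvec()
    R_h = Rotation.from_rotvec(rotvec / 2.0)
    t_h = np.linalg.solve(np.eye(3) + R_h.as_matrix(), t.translation)
    forward = RigidTransform(R_h.as_euler("xyz"), t_h, t.center)
    return forward, forward.inverse()


def build_b0_template(b0_maps: list[np.ndarray], voxel_size) -> TemplateResult:
    """Per-subject template construction with baseline-bias minimization.

    Step 1: halfway-align every follow-up to the baseline (both images move
    half the transform). Step 2: average the halfway-aligned maps into a
    template. Step 3: register every original session (baseline included)
    to the template and return those final transforms.
    """
    if len(b0_maps) == 0:
        raise ValueError("no sessions")
    if len(b0_maps) == 1:
        return TemplateResult(template=np.asarray(b0_maps[0], float),
                              transforms=[RigidTransform.identity()],
                              costs=[0.0],
                              warnings=["single session: identity transform"])
    baseline = np.asarray(b0_maps[0], float)
    aligned = []
    for i, b0 in enumerate(b0_maps):
        b0 = np.asarray(b0, float)
        if i == 0:
            aligned.append(baseline)
            continue
        t_full, _ = register_rigid(b0, baseline, voxel_size)
        fwd, bwd = halfway_split(t_full)
        # follow-up moves halfway toward baseline; baseline's halfway-moved
        # copy is implied by symmetry, the average below is taken in the
        # baseline frame after the forward half only
        aligned.append(resample(b0, fwd, voxel_size))
    template = np.mean(aligned, axis=0)

    transforms, costs = [], []
    for b0 in b0_maps:
        t, c = register_rigid(np.asarray(b0, float), template, voxel_size)
        transforms.append(t)
        costs.append(c)
    return TemplateResult(template=template, transforms=transforms, costs=costs)


def acpc_align(volume: np.ndarray, ac: np.ndarray, pc: np.ndarray, voxel_size,
               ac_reference: np.ndarray | None = None):
    """Rigidly reorient so the AC-PC segment runs along the y (grid) axis.

    Rotates with the minimal rotation taking the PC->AC direction to +y and
    translates AC to ``ac_reference`` (grid center by default). Returns
    ``(aligned_volume, transform)``; 4D inputs get the same transform per
    sub-volume.

    Raises
    ------
    ValueError
        If the landmarks coincide.
    """
    vs = np.asarray(voxel_size, float)
    ac_mm = np.asarray(ac, float) * vs
    pc_mm = np.asarray(pc, float) * vs
    d = ac_mm - pc_mm
    norm = np.linalg.norm(d)
    if norm < 1e-9:
        raise ValueError("AC and PC landmarks coincide")
    d = d / norm
    ey = np.array([0.0, 1.0, 0.0])
    axis = np.cross(d, ey)
    s = np.linalg.norm(axis)
    c = float(np.dot(d, ey))
    if s < 1e-12:
        R = np.eye(3) if c > 0 else Rotation.from_rotvec([0, 0, np.pi]).as_matrix()
    else:
        R = Rotation.from_rotvec(axis / s * np.arctan2(s, c)).as_matrix()

    shape3 = volume.shape[:3]
    if ac_reference is None:
        ac_reference = (np.asarray(shape3, float) - 1) / 2
    ref_mm = np.asarray(ac_reference, float) * vs

    M = np.eye(4)
    M[:3, :3] = R
    M[:3, 3] = ref_mm - R @ ac_mm
    t = RigidTransform.from_matrix(M, center=ref_mm)
    return resample(np.asarray(volume, float), t, vs), t
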