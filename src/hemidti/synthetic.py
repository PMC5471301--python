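"""Synthetic diffusion-weighted cohorts with known ground truth.

Builds mirror-symmetric white-matter phantoms on a regular grid, inserts an
isotropic tumor sphere with a local anisotropy depression, applies a
calibrated hemispheric anisotropy reduction, and simulates the
monoexponential tensor signal under Rician noise. Cohort generation draws
per-session target asymmetries from configurable group distributions and
solves for the reduction factor that realizes each target exactly in the
noiseless phantom.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtri

from . import dti

__all__ = [
    "GradientScheme",
    "PhantomSpec",
    "PhantomGroundTruth",
    "CohortSpec",
    "SubjectSession",
    "DWIVolume",
    "make_gradient_scheme",
    "build_phantom",
    "simulate_dwi",
    "make_longitudinal_cohort",
    "simulate_longitudinal_scalars",
    "CROSS_SECTIONAL_PRESET",
    "LONGITUDINAL_PRESET",
    "DEFAULT_NOISE_SIGMA",
    "DEFAULT_S0",
]

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))

DEFAULT_S0 = 1000.0
DEFAULT_NOISE_SIGMA = 20.0
FA_TRUTH_THRESHOLD = 0.2

# Group-level asymmetry presets used to drive cohort simulation.
CROSS_SECTIONAL_PRESET = {
    "pre_mean": 0.007, "pre_sd": 0.008, "n_pre": 10,
    "post_mean": 0.021, "post_sd": 0.013, "n_post": 11,
    "n_controls": 13,
}

# Longitudinal progression preset: session asymmetry =
# intercept + subject effect + slope * dt + residual noise,
# with post-RT scans clustered per subject the way long serial
# follow-up concentrates scans on a few subjects.
LONGITUDINAL_PRESET = {
    "n_pre": 12,
    "n_post": 38,
    "intercept": 0.007,
    "slope": 0.0002,          # asymmetry units per month
    "resid_sd": 0.008,
    "subject_sd": 0.008,
    "pre_mean": 0.007,
    "pre_sd": 0.008,
    "dt_min": 2.0,
    "dt_max": 72.0,
    "dt_span": 40.0,
    "post_scans_per_subject": (1, 1, 1, 1, 1, 1, 1, 2, 2, 4, 10, 8, 4, 1),
}


@dataclass(frozen=True)
class GradientScheme:
    """Diffusion directions and b-values, one entry per acquired volume.

    b0 volumes lead with zero direction vectors; the remaining entries are
    unit vectors.
    """

    directions: np.ndarray  # (nvol, 3)
    bvalues: np.ndarray  # (nvol,)
    n_b0: int

    def __post_init__(self):
        d = np.asarray(self.directions, dtype=float)
        b = np.asarray(self.bvalues, dtype=float)
        object.__setattr__(self, "directions", d)
        object.__setattr__(self, "bvalues", b)
        if len(d) != len(b):
            raise ValueError("directions and bvalues must have equal length")
        if np.any(b < 0):
            raise ValueError("b-values must be nonnegative")
        norms = np.linalg.norm(d[b > 0], axis=1)
        if norms.size and np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("nonzero-b directions must be unit vectors")

    @property
    def n_volumes(self) -> int:
        return len(self.bvalues)


def make_gradient_scheme(n_directions: int = 48, b: float = 800.0,
                         n_b0: int = 4) -> GradientScheme:
    """Deterministic quasi-uniform scheme via a golden-spiral point set.

    Raises
    ------
    ValueError
        If fewer than 6 directions are requested (tensor underdetermined).
    """
    if n_directions < 6:
        raise ValueError("invalid scheme: tensor fit needs >= 6 directions")
    i = np.arange(n_directions)
    z = 1.0 - 2.0 * (i + 0.5) / n_directions
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    phi = GOLDEN_ANGLE * i
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    directions = np.vstack([np.zeros((n_b0, 3)), dirs])
    bvalues = np.concatenate([np.zeros(n_b0), np.full(n_directions, float(b))])
    return GradientScheme(directions=directions, bvalues=bvalues, n_b0=n_b0)


@dataclass
class PhantomSpec:
    """Geometry and effect parameters of one synthetic brain phantom."""

    grid_shape: tuple[int, int, int] = (48, 48, 24)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.8)
    wm_eigenvalues: tuple[float, float, float] = (1.7e-3, 3.0e-4, 3.0e-4)
    tumor_center: tuple[float, float, float] | None = None  # voxel coords
    tumor_radius: float = 0.0  # mm; 0 disables the tumor
    tumor_hemisphere: str | None = None  # "left" | "right" | None
    fa_reduction_factor: float = 0.0  # blend of tumor-hemisphere WM toward isotropy
    contralateral_reduction_factor: float = 0.0  # same blend on the healthy side
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    s0: float = DEFAULT_S0
    local_depression: float = 0.08  # peak extra blend just outside the tumor rim
    texture_amp: float = 0.12  # mirror-symmetric S0 modulation amplitude

    def __post_init__(self):
        lam = tuple(float(v) for v in self.wm_eigenvalues)
        if any(v <= 0 for v in lam) or not (lam[0] >= lam[1] >= lam[2]):
            raise ValueError("wm_eigenvalues must be positive and sorted descending")
        if not 0.0 <= self.fa_reduction_factor <= 1.0:
            raise ValueError("fa_reduction_factor must be in [0, 1]")
        if not 0.0 <= self.contralateral_reduction_factor <= 1.0:
            raise ValueError("contralateral_reduction_factor must be in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.tumor_center is not None:
            if self.tumor_radius <= 0:
                raise ValueError("tumor_radius must be > 0 when a tumor is present")
            if self.tumor_hemisphere not in ("left", "right"):
                raise ValueError("tumor_hemisphere must be 'left' or 'right'")


@dataclass
class PhantomGroundTruth:
    """Noiseless truth of a phantom: tensors, labels, masks and the true asymmetry."""

    tensor_field: np.ndarray  # (nx, ny, nz, 3, 3), mm^2/s
    eigenvalues: np.ndarray  # (nx, ny, nz, 3) descending; zero outside brain
    tissue_mask: np.ndarray  # 0 background, 1 wm, 2 tumor
    hemisphere_masks: tuple[np.ndarray, np.ndarray]  # (left, right)
    true_global_delta_fa: float
    s0_map: np.ndarray
    midsagittal_x: float
    voxel_size: tuple[float, float, float]
    spec: PhantomSpec
    ac_landmark: np.ndarray  # voxel coords, on the midsagittal plane
    pc_landmark: np.ndarray

    @property
    def brain_mask(self) -> np.ndarray:
        return self.tissue_mask > 0

    @property
    def tumor_mask(self) -> np.ndarray:
        return self.tissue_mask == 2

    def true_fa_map(self) -> np.ndarray:
        lam = self.eigenvalues
        fa = dti.fa_from_eigenvalues(lam[..., 0], lam[..., 1], lam[..., 2])
        return np.where(self.brain_mask, fa, 0.0)


@dataclass
class DWIVolume:
    """Simulated or loaded 4D diffusion-weighted data."""

    data: np.ndarray  # (nx, ny, nz, nvol)
    scheme: GradientScheme
    voxel_size: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self):
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size) + [1.0])


@dataclass
class SubjectSession:
    """One scan session with metadata and file references."""

    subject_id: str
    session_id: str
    group: str  # patient | control
    rt_status: str  # none | pre | post
    delta_t_months: float
    tumor_hemisphere: str  # left | right | none
    dwi_path: str = ""
    bval_path: str = ""
    bvec_path: str = ""
    tumor_mask_path: str = ""

    def __post_init__(self):
        if self.group not in ("patient", "control"):
            raise ValueError(f"invalid group {self.group!r}")
        if self.rt_status not in ("none", "pre", "post"):
            raise ValueError(f"invalid rt_status {self.rt_status!r}")
        if (self.rt_status == "none") != (self.group == "control"):
            raise ValueError("rt_status 'none' if and only if group is 'control'")
        if self.delta_t_months < 0:
            raise ValueError("delta_t_months must be >= 0")
        if self.rt_status in ("none", "pre") and self.delta_t_months != 0:
            raise ValueError("delta_t_months must be 0 for pre-RT/control sessions")
        if self.tumor_hemisphere not in ("left", "right", "none"):
            raise ValueError(f"invalid tumor_hemisphere {self.tumor_hemisphere!r}")


@dataclass
class CohortSpec:
    """Counts, timing and target asymmetry distributions of a simulated cohort."""

    n_controls: int = 13
    n_pre_rt: int = 10
    n_post_rt: int = 11
    post_rt_delta_t: list[float] | None = None  # months; drawn if None
    target_pre_mean: float = CROSS_SECTIONAL_PRESET["pre_mean"]
    target_pre_sd: float = CROSS_SECTIONAL_PRESET["pre_sd"]
    target_post_mean: float = CROSS_SECTIONAL_PRESET["post_mean"]
    target_post_sd: float = CROSS_SECTIONAL_PRESET["post_sd"]
    progression_slope: float = 0.0  # asymmetry per month added to post targets
    seed: int = 0
    grid_shape: tuple[int, int, int] = (48, 48, 24)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.8)
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    stratified_targets: bool = True

    def __post_init__(self):
        if min(self.n_controls, self.n_pre_rt, self.n_post_rt) < 0:
            raise ValueError("cohort counts must be >= 0")
        if self.post_rt_delta_t is not None and len(self.post_rt_delta_t) != self.n_post_rt:
            raise ValueError("post_rt_delta_t length must equal n_post_rt")


# ---------------------------------------------------------------------------
# phantom construction


def _grid_coords(shape):
    return np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")


def _brain_geometry(spec: PhantomSpec):
    """Ellipsoidal brain mask and mirror-symmetric S0 texture."""
    nx, ny, nz = spec.grid_shape
    vx, vy, vz = spec.voxel_size
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    X, Y, Z = _grid_coords(spec.grid_shape)
    semi = (0.90 * nx * vx / 2, 0.94 * ny * vy / 2, 0.88 * nz * vz / 2)
    u = (X - cx) * vx / semi[0]
    v = (Y - cy) * vy / semi[1]
    w = (Z - cz) * vz / semi[2]
    rho2 = u * u + v * v + w * w
    brain = rho2 <= 1.0
    # texture is an even function of (x - cx): mirror symmetric by construction
    texture = 1.0 + spec.texture_amp * (
        0.6 * np.sin(2 * np.pi * Y / ny)
        + 0.5 * np.cos(2 * np.pi * Z / nz)
        + 0.4 * np.cos(3.0 * u * u + 1.0)
        - 0.35 * rho2
    )
    s0_map = np.where(brain, spec.s0 * texture, 0.0)
    if np.any(s0_map[brain] <= 0):
        raise ValueError("texture amplitude too large: nonpositive S0 inside brain")
    return brain, s0_map, (cx, cy, cz), rho2


def _wm_axes(spec: PhantomSpec):
    """Smoothly varying principal axis confined to the y-z plane.

    Axes with no x component are invariant under midsagittal reflection,
    which keeps the noiseless phantom exactly mirror symmetric.
    """
    nx, ny, nz = spec.grid_shape
    _, Y, Z = _grid_coords(spec.grid_shape)
    cz = (nz - 1) / 2.0
    psi = 0.7 * (Z - cz) / nz + 0.4 * np.sin(2 * np.pi * Y / ny)
    e = np.stack([np.zeros_like(psi), np.cos(psi), np.sin(psi)], axis=-1)
    return e


def build_phantom(spec: PhantomSpec) -> PhantomGroundTruth:
    """Construct the noiseless ground-truth phantom for one session.

    White matter carries the anisotropic tensor ``l2*I + (l1-l2) e e'`` with
    a smoothly varying in-plane axis ``e``; tumor voxels are isotropic at the
    WM mean diffusivity (ground-truth FA = 0 < 0.2); anisotropy reductions
    are linear blends of the tensor toward its isotropic part, which keeps
    MD constant and lets eigenvalues blend in closed form.

    Raises
    ------
    ValueError
        If the tumor sphere touches the midsagittal plane or lies in the
        wrong hemisphere.
    """
    nx, ny, nz = spec.grid_shape
    vx = spec.voxel_size[0]
    brain, s0_map, center, rho2 = _brain_geometry(spec)
    cx = center[0]
    X, Y, Z = _grid_coords(spec.grid_shape)

    lam = np.array(spec.wm_eigenvalues)
    md = lam.mean()

    tissue = np.where(brain, 1, 0).astype(np.uint8)
    blend = np.zeros(spec.grid_shape)  # per-voxel blend toward isotropy

    left = brain & (X < cx)
    right = brain & (X > cx)

    if spec.tumor_center is not None:
        tc = np.asarray(spec.tumor_center, dtype=float)
        offset_mm = (tc[0] - cx) * vx
        if abs(offset_mm) <= spec.tumor_radius:
            raise ValueError("tumor overlaps the midsagittal plane")
        side = "left" if offset_mm < 0 else "right"
        if side != spec.tumor_hemisphere:
            raise ValueError(
                f"tumor center lies in the {side} hemisphere, "
                f"not the stated {spec.tumor_hemisphere}"
            )
        d_mm = np.sqrt(
            ((X - tc[0]) * spec.voxel_size[0]) ** 2
            + ((Y - tc[1]) * spec.voxel_size[1]) ** 2
            + ((Z - tc[2]) * spec.voxel_size[2]) ** 2
        )
        tumor = brain & (d_mm <= spec.tumor_radius)
        tissue[tumor] = 2
        # local anisotropy depression just outside the rim, ipsilateral only
        ipsi = left if side == "left" else right
        ring = ipsi & ~tumor
        falloff = np.exp(-((d_mm - spec.tumor_radius) ** 2)
                         / (2.0 * (0.5 * spec.tumor_radius) ** 2))
        blend = np.where(ring, spec.local_depression * falloff, blend)
        ipsi_mask, contra_mask = (left, right) if side == "left" else (right, left)
    else:
        ipsi_mask, contra_mask = right, left  # unused when factors are 0

    # hemispheric blends compose multiplicatively with the local depression
    for m, f in ((ipsi_mask, spec.fa_reduction_factor),
                 (contra_mask, spec.contralateral_reduction_factor)):
        if f > 0:
            blend = np.where(m & (tissue == 1), 1.0 - (1.0 - blend) * (1.0 - f), blend)

    e = _wm_axes(spec)
    eye = np.eye(3)
    aniso = lam[1] * eye + (lam[0] - lam[1]) * np.einsum("...i,...j->...ij", e, e)
    iso = md * eye

    tensors = np.zeros(spec.grid_shape + (3, 3))
    wm = tissue == 1
    b3 = blend[..., None, None]
    tensors[wm] = ((1 - b3) * aniso + b3 * iso)[wm]
    tensors[tissue == 2] = iso

    # eigenvalues in closed form: blending preserves eigenvectors
    eigs = np.zeros(spec.grid_shape + (3,))
    lam_wm = (1 - blend[..., None]) * lam[None, None, None, :] + blend[..., None] * md
    eigs[wm] = lam_wm[wm]
    eigs[tissue == 2] = md

    hemis = (left, right)
    delta = _global_delta_from_eigs(eigs, tissue, hemis, spec.tumor_hemisphere)

    cy, cz = center[1], center[2]
    ac = np.array([cx, cy + 0.25 * ny, cz])
    pc = np.array([cx, cy - 0.10 * ny, cz])

    return PhantomGroundTruth(
        tensor_field=tensors, eigenvalues=eigs, tissue_mask=tissue,
        hemisphere_masks=hemis, true_global_delta_fa=delta, s0_map=s0_map,
        midsagittal_x=cx, voxel_size=spec.voxel_size, spec=spec,
        ac_landmark=ac, pc_landmark=pc,
    )


def _global_delta_from_eigs(eigs, tissue, hemis, tumor_hemisphere,
                            threshold=FA_TRUTH_THRESHOLD):
    """Healthy-minus-tumor-side mean FA over FA-thresholded brain voxels.

    Controls (no tumor hemisphere) use the fixed left-minus-right convention.
    """
    fa = dti.fa_from_eigenvalues(eigs[..., 0], eigs[..., 1], eigs[..., 2])
    fa = np.where(tissue > 0, fa, 0.0)
    left, right = hemis
    surv = fa > threshold
    mean_l = fa[left & surv].mean() if (left & surv).any() else np.nan
    mean_r = fa[right & surv].mean() if (right & surv).any() else np.nan
    if tumor_hemisphere == "left":
        return float(mean_r - mean_l)
    if tumor_hemisphere == "right":
        return float(mean_l - mean_r)
    return float(mean_l - mean_r)


# ---------------------------------------------------------------------------
# signal simulation


def simulate_dwi(phantom: PhantomGroundTruth, scheme: GradientScheme,
                 noise_sigma: float | None = None, seed: int = 0,
                 noise_model: str = "rician") -> DWIVolume:
    """Monoexponential tensor signal ``S = S0 exp(-b g' D g)`` with noise.

    Rician noise takes the magnitude of the complex Gaussian-perturbed
    signal; the Gaussian option adds real-valued noise (useful for analytic
    checks). ``noise_sigma`` defaults to the phantom spec's value.
    """
    if noise_sigma is None:
        noise_sigma = phantom.spec.noise_sigma
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be nonnegative")
    if noise_model not in ("rician", "gaussian"):
        raise ValueError(f"unknown noise model {noise_model!r}")

    g = scheme.directions
    b = scheme.bvalues
    # attenuation exponent b * g' D g via the 6 unique coefficients
    D = phantom.tensor_field
    c = np.stack([D[..., 0, 0], D[..., 1, 1], D[..., 2, 2],
                  D[..., 0, 1], D[..., 0, 2], D[..., 1, 2]], axis=-1)
    A = np.column_stack([
        b * g[:, 0] ** 2, b * g[:, 1] ** 2, b * g[:, 2] ** 2,
        2 * b * g[:, 0] * g[:, 1], 2 * b * g[:, 0] * g[:, 2],
        2 * b * g[:, 1] * g[:, 2],
    ])  # (nvol, 6)
    atten = np.exp(-np.tensordot(c, A, axes=([-1], [1])))  # (nx, ny, nz, nvol)
    signal = phantom.s0_map[..., None] * atten
    signal[~phantom.brain_mask] = 0.0

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        n1 = rng.normal(0.0, noise_sigma, signal.shape)
        if noise_model == "rician":
            n2 = rng.normal(0.0, noise_sigma, signal.shape)
            signal = np.sqrt((signal + n1) ** 2 + n2**2)
        else:
            signal = signal + n1
    return DWIVolume(data=signal, scheme=scheme, voxel_size=phantom.voxel_size)


# ---------------------------------------------------------------------------
# calibration of the reduction factor to a target asymmetry


def _delta_for_factor(base: PhantomGroundTruth, f: float, side: str) -> float:
    """True asymmetry after blending one hemisphere's WM by factor ``f``.

    Works on the closed-form eigenvalue field, so no eigendecomposition is
    needed inside the root search.
    """
    eigs = base.eigenvalues.copy()
    left, right = base.hemisphere_masks
    m = (left if side == "left" else right) & (base.tissue_mask == 1)
    md = eigs[m].mean(axis=-1, keepdims=True)
    eigs[m] = (1 - f) * eigs[m] + f * md
    return _global_delta_from_eigs(eigs, base.tissue_mask, base.hemisphere_masks,
                                   base.spec.tumor_hemisphere)


def _solve_factor(fun, target, delta0):
    """Root of ``fun(f) = target`` with adaptive bracket growth.

    ``fun`` is monotone over the operational range but becomes NaN once the
    blended hemisphere loses every suprathreshold voxel, so the bracket is
    grown geometrically and stops at the last finite point.
    """
    lo, flo = 0.0, delta0
    hi = 0.02
    while hi <= 0.95:
        fhi = fun(hi)
        if not np.isfinite(fhi):
            break
        if (flo - target) * (fhi - target) <= 0:
            return brentq(lambda f: fun(f) - target, lo, hi, xtol=1e-12)
        lo, flo = hi, fhi
        hi *= 2.0
    raise ValueError(f"target asymmetry {target} unreachable for this phantom")


def calibrate_reduction(spec: PhantomSpec, target_delta: float) -> PhantomSpec:
    """Return a spec whose noiseless phantom realizes ``target_delta``.

    Solves for the tumor-hemisphere blend factor; targets below the
    zero-reduction baseline (possible because the tumor's local depression
    already biases the asymmetry upward, while sampled targets may be
    negative) are realized by blending the contralateral hemisphere instead.
    """
    base = build_phantom(dataclasses.replace(
        spec, fa_reduction_factor=0.0, contralateral_reduction_factor=0.0))
    delta0 = base.true_global_delta_fa
    tumor_side = spec.tumor_hemisphere or "right"
    healthy_side = "left" if tumor_side == "right" else "right"
    if abs(target_delta - delta0) < 1e-12:
        return dataclasses.replace(spec, fa_reduction_factor=0.0,
                                   contralateral_reduction_factor=0.0)
    if target_delta > delta0:
        f = _solve_factor(lambda f: _delta_for_factor(base, f, tumor_side),
                          target_delta, delta0)
        return dataclasses.replace(spec, fa_reduction_factor=float(f),
                                   contralateral_reduction_factor=0.0)
    g = _solve_factor(lambda g: -_delta_for_factor(base, g, healthy_side),
                      -target_delta, -delta0)
    return dataclasses.replace(spec, fa_reduction_factor=0.0,
                               contralateral_reduction_factor=float(g))


# ---------------------------------------------------------------------------
# cohort generation


def _stratified_normal(rng, n, mean, sd, stratified=True):
    """Normal draws; stratified sampling pins the sample mean near ``mean``."""
    if n == 0:
        return np.array([])
    if not stratified:
        return rng.normal(mean, sd, n)
    u = (rng.permutation(n) + rng.uniform(0.0, 1.0, n)) / n
    return mean + sd * ndtri(u)


def _random_tumor(rng, spec_grid, voxel_size):
    """Random hemisphere, radius and center clear of the midline."""
    nx, ny, nz = spec_grid
    vx, vy, vz = voxel_size
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    side = "left" if rng.uniform() < 0.5 else "right"
    half_x = nx * vx / 2.0
    # radius and midline clearance scale with the grid so small desk-scale
    # phantoms stay valid
    radius = rng.uniform(0.14, 0.22) * half_x
    sign = -1.0 if side == "left" else 1.0
    off_mm = rng.uniform(radius + 0.05 * half_x, 0.85 * 0.90 * half_x - radius)
    center = (
        cx + sign * off_mm / vx,
        cy + rng.uniform(-0.12, 0.12) * ny,
        cz + rng.uniform(-0.10, 0.10) * nz,
    )
    return center, radius, side


def generate_session_phantom(rng, cohort: CohortSpec, target_delta: float | None,
                             with_tumor: bool) -> PhantomGroundTruth:
    """One session's calibrated ground-truth phantom."""
    kwargs = dict(grid_shape=cohort.grid_shape, voxel_size=cohort.voxel_size,
                  noise_sigma=cohort.noise_sigma)
    if with_tumor:
        center, radius, side = _random_tumor(rng, cohort.grid_shape, cohort.voxel_size)
        spec = PhantomSpec(tumor_center=center, tumor_radius=radius,
                           tumor_hemisphere=side, **kwargs)
        spec = calibrate_reduction(spec, target_delta)
    else:
        spec = PhantomSpec(**kwargs)
    return build_phantom(spec)


def make_longitudinal_cohort(cohort: CohortSpec, out_dir: str | Path | None = None,
                             scheme: GradientScheme | None = None):
    """Generate a full cohort: sessions, phantoms and the ground-truth table.

    Returns ``(sessions, truth_rows, phantoms)`` where ``truth_rows`` is a
    list of dicts (one per session) recording the true asymmetry and the
    calibrated factors. When ``out_dir`` is given, DWI NIfTI volumes,
    bvec/bval files, tumor masks, a TSV manifest and a JSON ground-truth
    table are written there.
    """
    if scheme is None:
        scheme = make_gradient_scheme()
    rng = np.random.default_rng(cohort.seed)

    sessions: list[SubjectSession] = []
    truth_rows: list[dict] = []
    phantoms: list[PhantomGroundTruth] = []

    pre_targets = _stratified_normal(rng, cohort.n_pre_rt, cohort.target_pre_mean,
                                     cohort.target_pre_sd, cohort.stratified_targets)
    post_base = _stratified_normal(rng, cohort.n_post_rt, cohort.target_post_mean,
                                   cohort.target_post_sd, cohort.stratified_targets)
    if cohort.post_rt_delta_t is not None:
        dts = np.asarray(cohort.post_rt_delta_t, dtype=float)
    else:
        dts = rng.uniform(LONGITUDINAL_PRESET["dt_min"],
                          LONGITUDINAL_PRESET["dt_max"], cohort.n_post_rt)
    post_targets = post_base + cohort.progression_slope * dts

    def add(subject, sess, group, status, dt, target, with_tumor):
        phantom = generate_session_phantom(rng, cohort, target, with_tumor)
        side = phantom.spec.tumor_hemisphere if with_tumor else "none"
        rec = SubjectSession(subject_id=subject, session_id=sess, group=group,
                             rt_status=status, delta_t_months=float(dt),
                             tumor_hemisphere=side)
        sessions.append(rec)
        phantoms.append(phantom)
        truth_rows.append({
            "subject_id": subject, "session_id": sess, "group": group,
            "rt_status": status, "delta_t_months": float(dt),
            "tumor_hemisphere": side,
            "true_global_delta_fa": phantom.true_global_delta_fa,
            "target_delta_fa": None if target is None else float(target),
            "fa_reduction_factor": phantom.spec.fa_reduction_factor,
            "contralateral_reduction_factor":
                phantom.spec.contralateral_reduction_factor,
        })

    for i in range(cohort.n_controls):
        add(f"C{i + 1:03d}", "ses-01", "control", "none", 0.0, None, False)
    for i, t in enumerate(pre_targets):
        add(f"P{i + 1:03d}", "ses-01", "patient", "pre", 0.0, t, True)
    for i, (t, dt) in enumerate(zip(post_targets, dts)):
        add(f"Q{i + 1:03d}", "ses-01", "patient", "post", dt, t, True)

    if out_dir is not None:
        _write_cohort(Path(out_dir), sessions, phantoms, truth_rows, scheme, rng)
    return sessions, truth_rows, phantoms


def _write_cohort(out_dir, sessions, phantoms, truth_rows, scheme, rng):
    from . import io as hio

    out_dir.mkdir(parents=True, exist_ok=True)
    for rec, phantom in zip(sessions, phantoms):
        seed = int(rng.integers(0, 2**31 - 1))
        dwi = simulate_dwi(phantom, scheme, seed=seed)
        stem = f"{rec.subject_id}_{rec.session_id}"
        rec.dwi_path = f"{stem}_dwi.nii"
        rec.bval_path = f"{stem}.bval"
        rec.bvec_path = f"{stem}.bvec"
        hio.save_nifti(out_dir / rec.dwi_path, dwi.data, phantom.voxel_size)
        hio.write_bval_bvec(out_dir / rec.bval_path, out_dir / rec.bvec_path, scheme)
        if phantom.tumor_mask.any():
            rec.tumor_mask_path = f"{stem}_tumor.nii"
            hio.save_nifti(out_dir / rec.tumor_mask_path,
                           phantom.tumor_mask.astype(np.uint8), phantom.voxel_size)
    hio.save_manifest(out_dir / "manifest.tsv", sessions)
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(truth_rows, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# scalar-level longitudinal simulation (no imaging)


def simulate_longitudinal_scalars(rng, n_pre=12, n_post=38, intercept=0.007,
                                  slope=0.0002, resid_sd=0.008, subject_sd=0.008,
                                  pre_mean=0.007, pre_sd=0.008, dt_min=2.0,
                                  dt_max=72.0, dt_span=40.0,
                                  post_scans_per_subject=LONGITUDINAL_PRESET[
                                      "post_scans_per_subject"]):
    """Draw (dt, asymmetry) pairs for one replicate of the serial cohort.

    Pre-RT sessions sit at dt = 0; post-RT sessions cluster within subjects
    (shared random intercept, increasing dt) following the configured
    scans-per-subject pattern.
    """
    dts = [np.zeros(n_pre)]
    vals = [rng.normal(pre_mean, pre_sd, n_pre)]
    n = 0
    for k in list(post_scans_per_subject) + [1] * n_post:
        k = min(int(k), n_post - n)
        if k <= 0:
            break
        n += k
        u = rng.normal(0.0, subject_sd)
        if k > 1:
            t0 = rng.uniform(dt_min, max(dt_min + 1.0, dt_max - 10.0))
            dt = np.sort(t0 + rng.uniform(0.0, dt_span, k))
        else:
            dt = np.array([rng.uniform(dt_min, dt_max)])
        dts.append(dt)
        vals.append(intercept + u + slope * dt + rng.normal(0.0, resid_sd, k))
    return np.concatenate(dts), np.concatenate(vals)
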