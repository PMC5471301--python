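"""Diffusion tensor estimation and scalar map computation.

Fits the single-tensor model ``S = S0 * exp(-b * g' D g)`` per voxel by
(weighted) log-linear least squares and derives the rotation-invariant
scalar maps FA, MD, AD and RD from the tensor eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "ScalarMap",
    "TensorField",
    "EigenSystem",
    "brain_mask",
    "design_matrix",
    "fit_tensor",
    "eigensystem",
    "fa_from_eigenvalues",
    "scalar_maps",
    "tensor_from_coeffs",
]

# eigenvalue floor in mm^2/s applied before scalar computation
EIG_FLOOR = 1e-12

# order of the 6 unique tensor coefficients throughout this package
COEFF_NAMES = ("dxx", "dyy", "dzz", "dxy", "dxz", "dyz")


@dataclass
class ScalarMap:
    """One 3D scalar map (FA, MD, AD or RD) with grid metadata."""

    data: np.ndarray
    metric: str
    voxel_size: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("ScalarMap data must be 3D")
        if self.metric not in ("FA", "MD", "AD", "RD", "b0", "other"):
            raise ValueError(f"unknown metric label {self.metric!r}")
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size) + [1.0])


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensor (6 unique coefficients) plus S0."""

    coeffs: np.ndarray  # (nx, ny, nz, 6) ordered as COEFF_NAMES
    s0: np.ndarray  # (nx, ny, nz)
    mask: np.ndarray  # boolean (nx, ny, nz)
    voxel_size: tuple[float, float, float]

    def tensors(self) -> np.ndarray:
        """Full (nx, ny, nz, 3, 3) symmetric tensor array."""
        return tensor_from_coeffs(self.coeffs)


@dataclass
class EigenSystem:
    """Sorted eigenvalues (descending) and principal eigenvector per voxel."""

    eigenvalues: np.ndarray  # (nx, ny, nz, 3), lam1 >= lam2 >= lam3
    principal: np.ndarray  # (nx, ny, nz, 3) unit vectors
    mask: np.ndarray
    voxel_size: tuple[float, float, float]
    degenerate: np.ndarray = field(default=None)  # all-zero-eigenvalue voxels


def tensor_from_coeffs(coeffs: np.ndarray) -> np.ndarray:
    """Expand (..., 6) unique coefficients into (..., 3, 3) symmetric tensors."""
    c = np.asarray(coeffs, dtype=float)
    out = np.zeros(c.shape[:-1] + (3, 3))
    out[..., 0, 0] = c[..., 0]
    out[..., 1, 1] = c[..., 1]
    out[..., 2, 2] = c[..., 2]
    out[..., 0, 1] = out[..., 1, 0] = c[..., 3]
    out[..., 0, 2] = out[..., 2, 0] = c[..., 4]
    out[..., 1, 2] = out[..., 2, 1] = c[..., 5]
    return out


def brain_mask(b0: np.ndarray, threshold_fraction: float = 0.1) -> np.ndarray:
    """Threshold a b0 map and keep the largest connected component.

    The threshold is ``threshold_fraction`` times the robust maximum
    (99th percentile) of the b0 intensities.

    Raises
    ------
    ValueError
        If no voxel survives the threshold.
    """
    b0 = np.asarray(b0, dtype=float)
    if np.any(b0 < 0):
        raise ValueError("b0 map must be nonnegative")
    robust_max = np.percentile(b0, 99)
    raw = b0 > threshold_fraction * robust_max
    if not raw.any() or robust_max <= 0:
        raise ValueError("brain mask is empty: b0 map has no signal")
    labels, n = ndimage.label(raw)
    if n == 0:
        raise ValueError("brain mask is empty")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    return labels == keep


def design_matrix(scheme) -> np.ndarray:
    """Log-linear design: row ``[1, -b gx^2, -b gy^2, -b gz^2, -2b gxgy, -2b gxgz, -2b gygz]``.

    Column 0 is the ln(S0) intercept; columns 1..6 multiply the tensor
    coefficients in :data:`COEFF_NAMES` order.
    """
    g = np.asarray(scheme.directions, dtype=float)
    b = np.asarray(scheme.bvalues, dtype=float)
    X = np.empty((len(b), 7))
    X[:, 0] = 1.0
    X[:, 1] = -b * g[:, 0] ** 2
    X[:, 2] = -b * g[:, 1] ** 2
    X[:, 3] = -b * g[:, 2] ** 2
    X[:, 4] = -2 * b * g[:, 0] * g[:, 1]
    X[:, 5] = -2 * b * g[:, 0] * g[:, 2]
    X[:, 6] = -2 * b * g[:, 1] * g[:, 2]
    return X


def fit_tensor(dwi: np.ndarray, scheme, mask: np.ndarray, *, wlls: bool = True,
               voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> TensorField:
    """Fit the diffusion tensor per in-mask voxel.

    Ordinary log-linear least squares followed (optionally) by one
    reweighted pass with weights equal to the squared predicted signal,
    the standard WLLS correction for log-transformed noise.

    Parameters
    ----------
    dwi : (nx, ny, nz, nvol) array
    scheme : GradientScheme
    mask : boolean (nx, ny, nz) array

    Raises
    ------
    ValueError
        If the gradient scheme cannot determine all 7 parameters.
    """
    dwi = np.asarray(dwi, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if dwi.ndim != 4:
        raise ValueError("dwi must be 4D")
    nzb = np.asarray(scheme.bvalues) > 0
    if np.count_nonzero(~nzb) < 1:
        raise ValueError("scheme deficiency: at least one b0 volume required")
    uniq = {tuple(np.round(d, 9)) for d in np.asarray(scheme.directions)[nzb]}
    if len(uniq) < 6:
        raise ValueError("scheme deficiency: need >= 6 distinct nonzero-b directions")
    X = design_matrix(scheme)
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError(
            "scheme deficiency: design matrix is singular "
            "(directions do not span the space of symmetric tensors)"
        )

    sig = dwi[mask]  # (nvox, nvol)
    sig = np.clip(sig, 1e-10, None)
    y = np.log(sig)
    theta = np.linalg.lstsq(X, y.T, rcond=None)[0].T  # (nvox, 7)

    if wlls:
        pred = X @ theta.T  # (nvol, nvox) log predictions
        w = np.exp(2 * pred.T)  # (nvox, nvol) weights ~ predicted signal^2
        XtWX = np.einsum("vi,nv,vj->nij", X, w, X)
        XtWy = np.einsum("vi,nv,nv->ni", X, w, y)
        theta = np.linalg.solve(XtWX, XtWy[..., None])[..., 0]

    shape = mask.shape
    coeffs = np.zeros(shape + (6,))
    s0 = np.zeros(shape)
    coeffs[mask] = theta[:, 1:]
    s0[mask] = np.exp(theta[:, 0])
    return TensorField(coeffs=coeffs, s0=s0, mask=mask, voxel_size=tuple(voxel_size))


def eigensystem(field: TensorField) -> EigenSystem:
    """Eigendecompose the tensor field; eigenvalues sorted descending.

    Negative eigenvalues are clamped to :data:`EIG_FLOOR` so downstream
    scalar maps stay defined.
    """
    D = field.tensors()[field.mask]
    vals, vecs = np.linalg.eigh(D)  # ascending
    vals = vals[:, ::-1]
    principal = vecs[:, :, ::-1][:, :, 0]
    degenerate_flat = np.all(np.abs(vals) < EIG_FLOOR, axis=1)
    vals = np.clip(vals, EIG_FLOOR, None)

    shape = field.mask.shape
    ev = np.zeros(shape + (3,))
    pv = np.zeros(shape + (3,))
    deg = np.zeros(shape, dtype=bool)
    ev[field.mask] = vals
    pv[field.mask] = principal
    deg[field.mask] = degenerate_flat
    return EigenSystem(eigenvalues=ev, principal=pv, mask=field.mask,
                       voxel_size=field.voxel_size, degenerate=deg)


def fa_from_eigenvalues(lam1, lam2, lam3):
    """Fractional anisotropy from sorted eigenvalues.

    ``FA = sqrt(((l1-l2)^2 + (l1-l3)^2 + (l3-l2)^2) / (2 (l1^2+l2^2+l3^2)))``

    All-zero eigenvalue triples map to FA = 0. Accepts scalars or arrays.
    """
    l1 = np.asarray(lam1, dtype=float)
    l2 = np.asarray(lam2, dtype=float)
    l3 = np.asarray(lam3, dtype=float)
    num = (l1 - l2) ** 2 + (l1 - l3) ** 2 + (l3 - l2) ** 2
    den = 2.0 * (l1**2 + l2**2 + l3**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        fa = np.sqrt(np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0))
    fa = np.clip(fa, 0.0, 1.0)
    if fa.ndim == 0:
        return float(fa)
    return fa


def scalar_maps(eig: EigenSystem) -> dict[str, ScalarMap]:
    """FA, MD, AD and RD maps from an eigensystem; zero outside the mask."""
    l1 = eig.eigenvalues[..., 0]
    l2 = eig.eigenvalues[..., 1]
    l3 = eig.eigenvalues[..., 2]
    m = eig.mask
    fa = np.where(m, fa_from_eigenvalues(l1, l2, l3), 0.0)
    if eig.degenerate is not None:
        fa = np.where(eig.degenerate, 0.0, fa)
    md = np.where(m, (l1 + l2 + l3) / 3.0, 0.0)
    ad = np.where(m, l1, 0.0)
    rd = np.where(m, (l2 + l3) / 2.0, 0.0)
    vs = eig.voxel_size
    return {
        "FA": ScalarMap(fa, "FA", vs),
        "MD": ScalarMap(md, "MD", vs),
        "AD": ScalarMap(ad, "AD", vs),
        "RD": ScalarMap(rd, "RD", vs),
    }
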