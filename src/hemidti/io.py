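"""File formats: NIfTI-1 volumes, FSL-dialect bvec/bval, TSV manifests."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .synthetic import DWIVolume, GradientScheme, SubjectSession

MANIFEST_COLUMNS = [
    "subject_id", "session_id", "group", "rt_status", "delta_t_months",
    "tumor_hemisphere", "dwi", "bval", "bvec", "tumor_mask",
]


def save_nifti(path, data, voxel_size, affine=None):
    if affine is None:
        affine = np.diag(list(voxel_size) + [1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.header.set_zooms(tuple(voxel_size) + ((1.0,) if np.asarray(data).ndim == 4 else ()))
    nib.save(img, str(path))


def load_nifti(path):
    """Return (data, voxel_size, affine)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    zooms = img.header.get_zooms()[:3]
    return data, tuple(float(z) for z in zooms), img.affine


def write_bval_bvec(bval_path, bvec_path, scheme: GradientScheme) -> None:
    """One whitespace-separated row of b-values; three rows of direction cosines."""
    b = np.asarray(scheme.bvalues, dtype=float)
    g = np.asarray(scheme.directions, dtype=float)
    with open(bval_path, "w") as fh:
        fh.write(" ".join(f"{v:g}" for v in b) + "\n")
    with open(bvec_path, "w") as fh:
        for axis in range(3):
            fh.write(" ".join(f"{v:.10f}" for v in g[:, axis]) + "\n")


def read_bval_bvec(bval_path, bvec_path) -> GradientScheme:
    b = np.loadtxt(bval_path, ndmin=1)
    g = np.loadtxt(bvec_path, ndmin=2)
    if g.shape[0] == 3:
        g = g.T  # FSL convention: three rows, one per axis
    if len(b) != len(g):
        raise ValueError("bval and bvec volume counts disagree")
    n_b0 = int(np.count_nonzero(b == 0))
    return GradientScheme(directions=g, bvalues=b, n_b0=n_b0)


def load_dwi(dwi_path, bval_path, bvec_path) -> DWIVolume:
    data, voxel_size, affine = load_nifti(dwi_path)
    scheme = read_bval_bvec(bval_path, bvec_path)
    if data.shape[-1] != scheme.n_volumes:
        raise ValueError(
            f"DWI has {data.shape[-1]} volumes but gradient table has {scheme.n_volumes}"
        )
    return DWIVolume(data=data, scheme=scheme, voxel_size=voxel_size, affine=affine)


def save_manifest(path, sessions: list[SubjectSession]) -> None:
    rows = [{
        "subject_id": s.subject_id, "session_id": s.session_id, "group": s.group,
        "rt_status": s.rt_status, "delta_t_months": s.delta_t_months,
        "tumor_hemisphere": s.tumor_hemisphere, "dwi": s.dwi_path,
        "bval": s.bval_path, "bvec": s.bvec_path, "tumor_mask": s.tumor_mask_path,
    } for s in sessions]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)


def load_manifest(path, check_files: bool = True) -> list[SubjectSession]:
    """Load and validate a cohort manifest.

    Errors name the offending row and column. Duplicate (subject, session)
    pairs, unknown status labels, status/timing contradictions and missing
    referenced files are all rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"manifest missing columns: {missing_cols}")

    seen = set()
    sessions = []
    missing_files = []
    for i, row in df.iterrows():
        key = (row["subject_id"], row["session_id"])
        if key in seen:
            raise ValueError(f"row {i}: duplicate session {key}")
        seen.add(key)
        try:
            dt = float(row["delta_t_months"])
        except ValueError as exc:
            raise ValueError(f"row {i}, column delta_t_months: {exc}") from exc
        try:
            s = SubjectSession(
                subject_id=row["subject_id"], session_id=row["session_id"],
                group=row["group"], rt_status=row["rt_status"], delta_t_months=dt,
                tumor_hemisphere=row["tumor_hemisphere"] or "none",
                dwi_path=row["dwi"], bval_path=row["bval"], bvec_path=row["bvec"],
                tumor_mask_path=row["tumor_mask"],
            )
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from exc
        if check_files:
            for col in ("dwi", "bval", "bvec", "tumor_mask"):
                rel = row[col]
                if rel and not (path.parent / rel).exists():
                    missing_files.append(f"row {i}, column {col}: {path.parent / rel}")
        sessions.append(s)
    if missing_files:
        raise FileNotFoundError("manifest references missing files:\n"
                                + "\n".join(missing_files))
    return sessions
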