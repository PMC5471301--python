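"""End-to-end orchestration: configuration, per-subject processing, cohort stats.

The pipeline processes each subject independently (template alignment when a
subject has several sessions, tensor fit, scalar maps, hemispheric
asymmetry), then pools sessions for the cross-sectional comparison, control
noise level and the longitudinal correlation. Per-subject failures are
isolated and recorded rather than aborting the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import align, dti, io, roi, stats
from . import synthetic as syn
from .synthetic import DWIVolume

logger = logging.getLogger("hemidti")

__all__ = ["PipelineConfig", "analyze_session", "run_pipeline",
           "run_synthetic_cohort"]


@dataclass
class PipelineConfig:
    """All tunables of the analysis, hashable for provenance."""

    fa_threshold: float = 0.2
    fwhm: float = 8.0
    alpha: float = 0.05
    min_cluster: int = 512
    radii: tuple[float, ...] = roi.DEFAULT_RADII_MM
    mask_threshold_fraction: float = 0.1
    seed: int = 0
    halfway: str = "symmetric"  # or "moving-only"
    wbss_test: str = "mann-whitney"

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "radii" in raw:
            raw["radii"] = tuple(raw["radii"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, default_flow_style=False)


def analyze_session(dwi: DWIVolume, config: PipelineConfig,
                    tumor_hemisphere: str = "none",
                    tumor_mask: np.ndarray | None = None,
                    midsagittal_x: float | None = None,
                    session_id: str = "") -> roi.DeltaResult:
    """Tensor fit, scalar maps and the global asymmetry for one session."""
    b0_mean = dwi.data[..., np.asarray(dwi.scheme.bvalues) == 0].mean(axis=-1)
    mask = dti.brain_mask(b0_mean, config.mask_threshold_fraction)
    field_ = dti.fit_tensor(dwi.data, dwi.scheme, mask, voxel_size=dwi.voxel_size)
    maps = dti.scalar_maps(dti.eigensystem(field_))
    if midsagittal_x is None:
        midsagittal_x = (dwi.data.shape[0] - 1) / 2.0
    hemis = roi.hemisphere_masks(mask, midsagittal_x)
    return roi.global_delta(maps, hemis, tumor_hemisphere,
                            fa_threshold=config.fa_threshold,
                            session_id=session_id, tumor_mask=tumor_mask)


def run_synthetic_cohort(cohort_spec, config: PipelineConfig | None = None,
                         scheme=None):
    """Generate a synthetic cohort in memory and analyze every session.

    Returns ``(sessions, truth_rows, phantoms, delta_results)``. Noise seeds
    derive deterministically from the cohort seed.
    """
    config = config or PipelineConfig()
    if scheme is None:
        scheme = syn.make_gradient_scheme()
    sessions, truth, phantoms = syn.make_longitudinal_cohort(cohort_spec,
                                                             scheme=scheme)
    rng = np.random.default_rng(cohort_spec.seed + 1)
    results = []
    for s, ph in zip(sessions, phantoms):
        dwi = syn.simulate_dwi(ph, scheme, seed=int(rng.integers(0, 2**31 - 1)))
        res = analyze_session(dwi, config, s.tumor_hemisphere,
                              ph.tumor_mask if ph.tumor_mask.any() else None,
                              ph.midsagittal_x,
                              f"{s.subject_id}/{s.session_id}")
        results.append(res)
    return sessions, truth, phantoms, results


def _subject_template_b0s(sessions, root, config):
    """Final per-session rigid transforms into the subject's b0 template."""
    b0s = []
    vs = None
    for s in sessions:
        d = io.load_dwi(root / s.dwi_path, root / s.bval_path, root / s.bvec_path)
        b0s.append(d.data[..., np.asarray(d.scheme.bvalues) == 0].mean(axis=-1))
        vs = d.voxel_size
    return align.build_b0_template(b0s, vs), vs


def run_pipeline(manifest_path, config: PipelineConfig, out_dir) -> dict:
    """Run the full analysis over a cohort manifest.

    Writes the per-session asymmetry table (TSV), the cohort statistics
    report (JSON, with the config hash) and a run log. Returns the report
    dict; the key ``n_failed`` counts subjects that errored and were
    skipped.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = Path(manifest_path)
    sessions = io.load_manifest(manifest_path)
    root = manifest_path.parent
    cfg_hash = config.config_hash()

    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    results: list[roi.DeltaResult] = []
    kept_sessions = []
    failures: dict[str, str] = {}

    by_subject: dict[str, list] = {}
    for s in sessions:
        by_subject.setdefault(s.subject_id, []).append(s)

    try:
        for subject_id, subj_sessions in by_subject.items():
            t0 = time.time()
            try:
                transforms = None
                if len(subj_sessions) >= 2:
                    tpl, vs = _subject_template_b0s(subj_sessions, root, config)
                    transforms = tpl.transforms
                for i, s in enumerate(subj_sessions):
                    dwi = io.load_dwi(root / s.dwi_path, root / s.bval_path,
                                      root / s.bvec_path)
                    tumor_mask = None
                    if s.tumor_mask_path:
                        tumor_mask = io.load_nifti(root / s.tumor_mask_path)[0] > 0.5
                    sid = f"{s.subject_id}/{s.session_id}"
                    res = _analyze_aligned(dwi, config, s, tumor_mask, sid,
                                           transforms[i] if transforms else None)
                    results.append(res)
                    kept_sessions.append(s)
                logger.info("subject %s done in %.1fs (%d sessions)",
                            subject_id, time.time() - t0, len(subj_sessions))
            except Exception as exc:  # noqa: BLE001 - isolate subject failures
                failures[subject_id] = str(exc)
                logger.warning("subject %s failed: %s", subject_id, exc)
    finally:
        logger.removeHandler(handler)
        handler.close()

    table = pd.DataFrame([{
        "subject_id": s.subject_id, "session_id": s.session_id,
        "group": s.group, "rt_status": s.rt_status,
        "delta_t_months": s.delta_t_months,
        "delta_fa": r.global_deltas.get("FA"),
        "delta_md": r.global_deltas.get("MD"),
        "delta_ad": r.global_deltas.get("AD"),
        "delta_rd": r.global_deltas.get("RD"),
        "n_voxels_healthy": r.n_voxels_healthy,
        "n_voxels_tumor_side": r.n_voxels_tumor_side,
        "valid": r.valid,
        "config_hash": cfg_hash,
    } for s, r in zip(kept_sessions, results)])
    table.to_csv(out_dir / "delta_results.tsv", sep="\t", index=False,
                 float_format="%.10g")

    report: dict = {"config_hash": cfg_hash, "n_sessions": len(results),
                    "n_failed": len(failures), "failures": failures}
    controls = [r.global_deltas["FA"] for s, r in zip(kept_sessions, results)
                if s.group == "control" and r.valid]
    if len(controls) >= 2:
        nl = stats.noise_level(controls)
        report["noise_level"] = {"max_abs": nl.max_abs, "sd": nl.sd,
                                 "percentile_95": nl.percentile_95}
    try:
        comparisons = {}
        for metric in ("FA", "MD", "AD", "RD"):
            gc = stats.crosssection(kept_sessions, results, metric)
            comparisons[metric] = {
                "n": list(gc.n), "means": list(gc.means), "sds": list(gc.sds),
                "U": gc.u_statistic, "p": gc.p_value, "method": gc.method,
            }
        report["crosssection"] = comparisons
    except ValueError as exc:
        report["crosssection_error"] = str(exc)
    try:
        overall, per_subject = stats.longitudinal(kept_sessions, results)
        report["longitudinal"] = {
            "n": overall.n, "spearman_c": overall.coefficient,
            "p": overall.p_value,
            "per_subject": {k: {"c": v.coefficient, "p": v.p_value}
                            for k, v in per_subject.items()},
        }
    except ValueError as exc:
        report["longitudinal_error"] = str(exc)

    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=float)
    config.to_yaml(out_dir / "config_used.yaml")
    return report


def _analyze_aligned(dwi, config, session, tumor_mask, session_id, transform):
    """Per-session analysis; scalar maps are resampled once when a template
    transform exists (native-space fit, single interpolation)."""
    if transform is None:
        return analyze_session(dwi, config, session.tumor_hemisphere, tumor_mask,
                               session_id=session_id)
    b0_mean = dwi.data[..., np.asarray(dwi.scheme.bvalues) == 0].mean(axis=-1)
    mask = dti.brain_mask(b0_mean, config.mask_threshold_fraction)
    field_ = dti.fit_tensor(dwi.data, dwi.scheme, mask, voxel_size=dwi.voxel_size)
    maps = dti.scalar_maps(dti.eigensystem(field_))
    res_maps = {}
    for k, m in maps.items():
        res_maps[k] = dti.ScalarMap(
            align.resample(m.data, transform, dwi.voxel_size), k, dwi.voxel_size)
    res_mask = align.resample(mask.astype(float), transform, dwi.voxel_size) > 0.5
    if tumor_mask is not None:
        tumor_mask = align.resample(tumor_mask.astype(float), transform,
                                    dwi.voxel_size) > 0.5
    midsag = (dwi.data.shape[0] - 1) / 2.0
    hemis = roi.hemisphere_masks(res_mask, midsag)
    return roi.global_delta(res_maps, hemis, session.tumor_hemisphere,
                            fa_threshold=config.fa_threshold,
                            session_id=session_id, tumor_mask=tumor_mask)
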