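"""Temporal preprocessing: dummy-volume discard, motion QC, smoothing,
linear detrending, band-pass filtering and nuisance regression.

Pipeline order is fixed: discard -> smooth -> detrend -> band-pass ->
nuisance regression.  The band-pass is a zero-phase FFT mask with a
raised-cosine taper; confound time series (white-matter mean, CSF mean,
six realignment parameters) are detrended and filtered identically
before the regression so the residuals stay inside the analysis band.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import StudyConfig
from .core_io import MaskVolume, MotionTrace, Study, SubjectRun, Volume4D
from .errors import BandError, InvalidVolumeError


# ---------------------------------------------------------------------------
# volume bookkeeping
# ---------------------------------------------------------------------------

def discard_initial(run: SubjectRun, n_discard: int) -> SubjectRun:
    """Drop the first ``n_discard`` volumes (and motion rows) of a run."""
    if run.volume.n_volumes <= n_discard:
        raise InvalidVolumeError(
            f"run has {run.volume.n_volumes} volumes, cannot discard {n_discard}"
        )
    if n_discard == 0:
        return run
    vol = Volume4D(
        data=run.volume.data[..., n_discard:],
        affine=run.volume.affine,
        tr_s=run.volume.tr_s,
    )
    motion = MotionTrace(params=run.motion.params[n_discard:])
    return SubjectRun(
        subject_id=run.subject_id, run_index=run.run_index,
        volume=vol, motion=motion,
    )


def run_duration_s(n_volumes: int, tr_s: float) -> int:
    """Scan time of ``n_volumes`` at repetition time ``tr_s``, in whole
    seconds (139 volumes at 2.64 s -> 367)."""
    if n_volumes < 0:
        raise ValueError("volume count cannot be negative")
    return int(round(n_volumes * tr_s))


# ---------------------------------------------------------------------------
# motion quality control
# ---------------------------------------------------------------------------

@dataclass
class MotionSummary:
    """Per-run head-motion QC summary."""

    scan_to_scan_mm: np.ndarray   # (t-1,) displacement between volumes
    mean_motion_mm: float
    n_flagged: int                # transitions above the flag threshold
    percent_flagged: float
    run_ok: bool                  # within the 2 mm / 2 degree run limits
    censor_after_index: int | None  # volumes to retain before first violation

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{
                "mean_motion_mm": self.mean_motion_mm,
                "n_flagged": self.n_flagged,
                "percent_flagged": self.percent_flagged,
                "run_ok": self.run_ok,
                "censor_after_index": self.censor_after_index,
            }]
        )


def scan_to_scan_displacement(
    motion: MotionTrace, rotation_radius_mm: float = 30.0
) -> np.ndarray:
    """Displacement between consecutive volumes.

    Euclidean norm of the translation increment, combined in quadrature
    with the rotation increment converted to arc length on a sphere of
    ``rotation_radius_mm`` (brain-scale radius, configurable).
    """
    if motion.n_volumes < 2:
        raise InvalidVolumeError("need at least 2 volumes for displacement")
    d = np.diff(motion.params, axis=0)
    trans = np.linalg.norm(d[:, :3], axis=1)
    rot_arc = np.linalg.norm(np.radians(d[:, 3:]), axis=1) * rotation_radius_mm
    return np.sqrt(trans**2 + rot_arc**2)


def percent_flagged(n_flagged: int, n_total: int) -> float:
    """Percentage of flagged scans, rounded to 2 decimals (3 of 5975 -> 0.05)."""
    if n_total <= 0:
        raise ZeroDivisionError("n_total must be positive")
    if not (0 <= n_flagged <= n_total):
        raise ValueError("need 0 <= n_flagged <= n_total")
    return round(100.0 * n_flagged / n_total, 2)


def motion_summary(motion: MotionTrace, cfg: StudyConfig) -> MotionSummary:
    """QC one motion trace against the study's limits.

    ``run_ok`` is False iff any absolute translation exceeds the 2 mm
    limit or any absolute rotation the 2 degree limit; in that case
    ``censor_after_index`` is the number of leading clean volumes (the
    0-based index of the first violating volume).
    """
    disp = scan_to_scan_displacement(motion, cfg.rotation_radius_mm)
    n_flag = int((disp > cfg.scan_to_scan_flag_mm).sum())
    viol = (
        (np.abs(motion.translations_mm) > cfg.motion_limit_mm).any(axis=1)
        | (np.abs(motion.rotations_deg) > cfg.motion_limit_deg).any(axis=1)
    )
    run_ok = not viol.any()
    censor = None if run_ok else int(np.argmax(viol))
    return MotionSummary(
        scan_to_scan_mm=disp,
        mean_motion_mm=float(disp.mean()),
        n_flagged=n_flag,
        percent_flagged=percent_flagged(n_flag, disp.size),
        run_ok=run_ok,
        censor_after_index=censor,
    )


# ---------------------------------------------------------------------------
# temporal filters
# ---------------------------------------------------------------------------

def detrend_linear(ts: np.ndarray, axis: int = -1) -> np.ndarray:
    """Residual of a least-squares line fit along ``axis``; output has zero
    mean and zero correlation with the time index."""
    ts = np.asarray(ts, dtype=float)
    n = ts.shape[axis]
    if n < 3:
        raise InvalidVolumeError(f"need at least 3 samples to detrend, got {n}")
    t = np.arange(n, dtype=float)
    t -= t.mean()
    ts = np.moveaxis(ts, axis, -1)
    mean = ts.mean(axis=-1, keepdims=True)
    slope = (ts - mean) @ t / (t @ t)
    out = ts - mean - slope[..., None] * t
    return np.moveaxis(out, -1, axis)


def bandpass_gain(freqs_hz: np.ndarray, low_hz: float, high_hz: float,
                  taper_hz: float = 0.005) -> np.ndarray:
    """Transfer function of the band-pass: unit gain inside the band with
    raised-cosine edges of total width ``taper_hz`` centred on each cutoff."""
    f = np.asarray(freqs_hz, dtype=float)
    g = np.zeros_like(f)
    h = taper_hz / 2.0
    g[(f >= low_hz + h) & (f <= high_hz - h)] = 1.0
    lo_edge = (f > low_hz - h) & (f < low_hz + h)
    g[lo_edge] = 0.5 * (1 - np.cos(np.pi * (f[lo_edge] - (low_hz - h)) / taper_hz))
    hi_edge = (f > high_hz - h) & (f < high_hz + h)
    g[hi_edge] = 0.5 * (1 + np.cos(np.pi * (f[hi_edge] - (high_hz - h)) / taper_hz))
    return g


def bandpass(ts: np.ndarray, tr_s: float, low_hz: float, high_hz: float,
             axis: int = -1, taper_hz: float = 0.005) -> np.ndarray:
    """Zero-phase FFT-domain band-pass filter along ``axis``."""
    nyq = 1.0 / (2.0 * tr_s)
    if not (0.0 < low_hz < high_hz < nyq):
        raise BandError(
            f"band ({low_hz}, {high_hz}) infeasible at TR {tr_s} s "
            f"(Nyquist {nyq:.4f} Hz)"
        )
    ts = np.asarray(ts, dtype=float)
    n = ts.shape[axis]
    freqs = np.fft.rfftfreq(n, d=tr_s)
    gain = bandpass_gain(freqs, low_hz, high_hz, taper_hz)
    spec = np.fft.rfft(ts, axis=axis)
    shape = [1] * ts.ndim
    shape[axis] = gain.size
    spec *= gain.reshape(shape)
    return np.fft.irfft(spec, n=n, axis=axis)


def gaussian_smooth(vol: Volume4D, fwhm_mm: float) -> Volume4D:
    """Per-volume 3D Gaussian smoothing with the kernel given in mm FWHM."""
    if fwhm_mm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm_mm == 0:
        return vol
    sigma_mm = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_vox = sigma_mm / vol.voxel_size_mm
    out = ndimage.gaussian_filter(
        np.asarray(vol.data, dtype=np.float32),
        sigma=(*sigma_vox, 0.0),
    )
    return Volume4D(data=out, affine=vol.affine, tr_s=vol.tr_s)


def nuisance_regress(Y: np.ndarray, confounds: np.ndarray) -> np.ndarray:
    """Residualise each row of ``Y`` (voxels x t) on the confound columns.

    An intercept column is added internally; rank-deficient designs are
    handled by the pseudo-inverse.  Residuals are orthogonal to every
    confound column to numerical precision.
    """
    Y = np.asarray(Y, dtype=float)
    C = np.atleast_2d(np.asarray(confounds, dtype=float))
    t = Y.shape[1]
    if C.shape[0] != t:
        raise ValueError(f"confounds have {C.shape[0]} rows, data has {t}")
    C = np.column_stack([np.ones(t), C])
    if t <= C.shape[1]:
        raise InvalidVolumeError(
            f"need t > k+1 (t={t}, k={C.shape[1] - 1} incl. intercept)"
        )
    beta = np.linalg.pinv(C) @ Y.T      # (k+1, voxels)
    return Y - (C @ beta).T


# ---------------------------------------------------------------------------
# run- and study-level drivers
# ---------------------------------------------------------------------------

def _eroded_or_full(mask: np.ndarray, iterations: int = 1) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask, iterations=iterations)
    return eroded if eroded.any() else mask


@dataclass
class PreprocessedRun:
    """Brain-masked, fully preprocessed run: (t, n_brain_voxels) matrix."""

    subject_id: str
    run_index: int
    data: np.ndarray
    motion_qc: MotionSummary


def preprocess_run(run: SubjectRun, masks: dict[str, MaskVolume],
                   cfg: StudyConfig) -> PreprocessedRun:
    """Full temporal pipeline for one run.

    discard -> smooth -> detrend -> band-pass -> nuisance regression,
    with whole-run truncation at the first motion-limit violation (no
    mid-run volume deletion).  Returns the brain-masked (t, V) matrix.
    """
    run = discard_initial(run, cfg.discard_initial)
    qc = motion_summary(run.motion, cfg)
    if not qc.run_ok:
        if qc.censor_after_index < max(16, cfg.discard_initial + 3):
            raise InvalidVolumeError(
                f"{run.subject_id} run {run.run_index}: motion violation at "
                f"volume {qc.censor_after_index}, too few clean volumes"
            )
        run = SubjectRun(
            subject_id=run.subject_id, run_index=run.run_index,
            volume=Volume4D(
                data=run.volume.data[..., : qc.censor_after_index],
                affine=run.volume.affine, tr_s=run.volume.tr_s,
            ),
            motion=MotionTrace(params=run.motion.params[: qc.censor_after_index]),
        )

    vol = gaussian_smooth(run.volume, cfg.smooth_fwhm_mm)
    brain = masks["brain"].data
    Y = vol.data[brain].astype(float)          # (V, t)

    Y = detrend_linear(Y, axis=-1)
    low, high = cfg.band_hz
    Y = bandpass(Y, cfg.tr_s, low, high, axis=-1)

    # confound signals come from eroded tissue masks so that smoothing
    # spill-over from grey matter does not leak neural signal into the
    # nuisance regressors (falling back to the full mask if erosion
    # empties it)
    wm = _eroded_or_full(masks["white"].data)[brain]
    csf = _eroded_or_full(masks["csf"].data)[brain]
    conf = [Y[wm].mean(axis=0), Y[csf].mean(axis=0)]
    mp = detrend_linear(run.motion.params, axis=0)
    mp = bandpass(mp, cfg.tr_s, low, high, axis=0)
    confounds = np.column_stack(conf + [mp])
    Y = nuisance_regress(Y, confounds)

    return PreprocessedRun(
        subject_id=run.subject_id, run_index=run.run_index,
        data=Y.T, motion_qc=qc,
    )


def preprocess_study(study: Study) -> list[PreprocessedRun]:
    """Preprocess every run of a study against its brain/WM/CSF masks."""
    return [preprocess_run(r, study.masks, study.config) for r in study.runs]


def motion_report(study: Study) -> pd.DataFrame:
    """Per-run motion QC table (one row per run, after dummy discard)."""
    rows = []
    for r in study.runs:
        rr = discard_initial(r, study.config.discard_initial)
        s = motion_summary(rr.motion, study.config)
        rows.append({
            "subject": r.subject_id, "run": r.run_index,
            "mean_motion_mm": s.mean_motion_mm,
            "n_flagged": s.n_flagged,
            "percent_flagged": s.percent_flagged,
            "run_ok": s.run_ok,
            "censor_after_index": s.censor_after_index,
        })
    return pd.DataFrame(rows)
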