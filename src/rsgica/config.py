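"""Study-level configuration.

All analysis constants of the pipeline live in one validated dataclass:
repetition time, dummy-volume discard, the 0.01-0.1 Hz band, smoothing
kernel, ICA model orders, the dual FDR thresholds, the DSC matching and
consistency cutoffs, and the motion QC limits.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class StudyConfig:
    """Analysis parameters for one resting-state study.

    Defaults reproduce the awake-dog study design this package emulates:
    TR 2.64 s with the first 5 volumes discarded, 0.01-0.1 Hz band-pass,
    4 mm FWHM smoothing, model orders 10/15/20, voxel FDR q=0.001 with
    cluster FDR q=0.005, DSC match threshold 0.3 and cross-run consistency
    threshold 0.25, and per-run motion limits of 2 mm / 2 degrees with a
    0.2 mm scan-to-scan flag.
    """

    tr_s: float = 2.64
    discard_initial: int = 5
    band_hz: tuple[float, float] = (0.01, 0.1)
    smooth_fwhm_mm: float = 4.0
    model_orders: tuple[int, ...] = (10, 15, 20)
    q_voxel: float = 0.001
    q_cluster: float = 0.005
    tau_match: float = 0.3
    tau_consistency: float = 0.25
    motion_limit_mm: float = 2.0
    motion_limit_deg: float = 2.0
    scan_to_scan_flag_mm: float = 0.2
    # radius (mm) used to convert rotation increments to arc displacement
    rotation_radius_mm: float = 30.0
    rotations_in_radians: bool = False
    n_permutations: int = 1000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.band_hz
        nyquist = 1.0 / (2.0 * self.tr_s)
        if not (0.0 < low < high < nyquist):
            raise ValueError(
                f"band {self.band_hz} infeasible: need 0 < low < high < "
                f"Nyquist ({nyquist:.4f} Hz at TR {self.tr_s} s)"
            )
        for name in ("q_voxel", "q_cluster", "tau_match", "tau_consistency"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name}={v} must lie in (0, 1)")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if self.discard_initial < 0:
            raise ValueError("discard_initial must be >= 0")

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_s)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["band_hz"] = list(self.band_hz)
        d["model_orders"] = list(self.model_orders)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        known = {f for f in cls.__dataclass_fields__}  # noqa: C401
        kwargs = {k: v for k, v in d.items() if k in known}
        if "band_hz" in kwargs:
            kwargs["band_hz"] = tuple(kwargs["band_hz"])
        if "model_orders" in kwargs:
            kwargs["model_orders"] = tuple(kwargs["model_orders"])
        return cls(**kwargs)
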