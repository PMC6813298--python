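"""Multi-subject synthetic resting-state phantom with known ground truth.

Emulates the study design the pipeline was built for: 22 subjects, two
runs each, 139 acquired volumes at TR 2.64 s (first 5 discarded
downstream), band-limited 0.01-0.1 Hz source dynamics, white-matter/CSF
nuisance structure, slow drift, bounded head-motion traces, and three
artifact sources with the spatial signatures the screening stage looks
for: a ring at the brain edge (residual motion), a ventral vessel blob,
and an anterior blob beyond the susceptibility boundary.

Everything is deterministic given a seed; the generator emits the same
NIfTI + motion-text + manifest formats that :mod:`rsgica.core_io` reads.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .config import StudyConfig
from .core_io import (
    MaskVolume,
    MotionTrace,
    Study,
    SubjectRun,
    Volume4D,
    save_mask,
    save_motion,
    save_volume,
)
from .errors import BandError, PlacementError

DEFAULT_GRID = (28, 28, 14)
DEFAULT_VOXEL_MM = (2.0, 2.0, 2.5)
#: blob radii stop growing beyond this grid so that a larger grid buys
#: separation between sources instead of larger sources
_RADII_REF_GRID = (24, 24, 12)

NETWORK = "network"
RING = "ring_artifact"
VESSEL = "vessel_artifact"
SUSCEPTIBILITY = "susceptibility_artifact"

#: network template slots: (centre offsets in brain-semiaxis units, bilateral?)
#: the bilateral pair owns the lateral positions (auditory-like); the
#: unilateral networks sit on the midline, separated along y and z, so
#: no two networks share a lateral position
_NETWORK_SLOTS = [
    ((0.50, 0.00, 0.40), True),     # bilateral pair (mirror-symmetric in x)
    ((0.00, -0.55, -0.40), False),  # posterior ventral midline
    ((0.00, -0.40, 0.55), False),   # posterior dorsal midline
    ((0.00, 0.35, 0.40), False),    # anterior dorsal midline
    ((0.00, 0.05, -0.58), False),   # ventral midline
    ((-0.52, -0.05, -0.30), False),
]


@dataclass
class PhantomTruth:
    """Ground truth of a simulated study."""

    source_maps: np.ndarray          # (n_sources, x, y, z)
    labels: list[str]                # per-source label
    timecourses: dict                # (subject_id, run_index) -> (t, n_sources)
    subject_gains: dict              # subject_id -> (n_sources,) gains
    noise_sigma: dict                # (subject_id, run_index) -> float
    grid_shape: tuple
    affine: np.ndarray = None

    @property
    def network_indices(self) -> list[int]:
        return [i for i, l in enumerate(self.labels) if l == NETWORK]

    @property
    def n_sources(self) -> int:
        return self.source_maps.shape[0]


def default_affine(voxel_mm=DEFAULT_VOXEL_MM) -> np.ndarray:
    aff = np.diag([*voxel_mm, 1.0])
    return aff


def _ellipsoid(grid_shape, center, semi) -> np.ndarray:
    idx = np.indices(grid_shape, dtype=float)
    d2 = sum(((idx[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    return d2 <= 1.0


def brain_geometry(grid_shape=DEFAULT_GRID):
    """Centre and semi-axes (voxels) of the phantom's ellipsoidal brain."""
    gx, gy, gz = grid_shape
    center = ((gx - 1) / 2.0, (gy - 1) / 2.0, (gz - 1) / 2.0)
    semi = (0.40 * gx, 0.44 * gy, 0.42 * gz)
    return center, semi


def make_masks(grid_shape=DEFAULT_GRID, voxel_mm=DEFAULT_VOXEL_MM) -> dict[str, MaskVolume]:
    """Deterministic anatomical-style masks on the phantom grid.

    +y is anterior and low z is ventral.  The susceptibility-boundary mask
    marks the anterior slab beyond the artifact line; the vessel mask is a
    ventral blob; white matter is an inner shell around a small central
    CSF compartment.
    """
    aff = default_affine(voxel_mm)
    center, semi = brain_geometry(grid_shape)
    gx, gy, gz = grid_shape

    brain = _ellipsoid(grid_shape, center, semi)
    inner = _ellipsoid(grid_shape, center, tuple(0.60 * s for s in semi))
    csf = _ellipsoid(
        grid_shape,
        (center[0], center[1] - 0.04 * gy, center[2]),
        (0.095 * gx, 0.115 * gy, 0.13 * gz),
    ) & brain
    white = inner & ~csf & brain
    grey = brain & ~white & ~csf

    ys = np.indices(grid_shape)[1]
    susceptibility = brain & (ys >= center[1] + 0.52 * semi[1])

    # ventral vascular compartment; disjoint from WM/CSF so that vessel
    # signal cannot enter the nuisance regressors
    vessel = _ellipsoid(
        grid_shape,
        (center[0], center[1] + 0.06 * gy, 0.16 * gz),
        (0.15 * gx, 0.17 * gy, 0.16 * gz),
    ) & brain & ~white & ~csf

    out = {}
    for role, arr in [
        ("brain", brain), ("grey", grey), ("white", white), ("csf", csf),
        ("susceptibility_boundary", susceptibility), ("vessel", vessel),
    ]:
        out[role] = MaskVolume(data=arr.astype(np.uint8), affine=aff, role=role)
    return out


def ring_mask(brain: np.ndarray, width: int = 2) -> np.ndarray:
    """Rim of the brain mask: brain minus its erosion by ``width`` voxels."""
    eroded = ndimage.binary_erosion(brain, iterations=width)
    return brain & ~eroded


def inplane_ring_mask(brain: np.ndarray, width: int = 1,
                      min_slice_area: int = 40) -> np.ndarray:
    """Per-slice (axial) rim of the brain mask.

    Edge rings from residual in-plane motion follow the brain outline
    within each slice; thin apex/base slices (below ``min_slice_area``
    voxels), which would be rim in their entirety, are skipped.
    """
    out = np.zeros_like(brain, dtype=bool)
    for z in range(brain.shape[2]):
        sl = brain[:, :, z]
        if sl.sum() < min_slice_area:
            continue
        out[:, :, z] = sl & ~ndimage.binary_erosion(sl, iterations=width)
    return out


def _blob(grid_shape, center, radii, brain) -> np.ndarray:
    m = _ellipsoid(grid_shape, center, radii).astype(float)
    m = ndimage.gaussian_filter(m, sigma=1.0)
    m[~brain] = 0.0
    peak = m.max()
    if peak <= 0:
        raise PlacementError(f"blob at {center} fell outside the brain")
    return m / peak


def _support(m: np.ndarray) -> np.ndarray:
    return m > 0.1


def make_sources(
    grid_shape=DEFAULT_GRID,
    n_networks: int = 4,
    seed: int = 0,
    masks: dict[str, MaskVolume] | None = None,
    max_retries: int = 20,
):
    """Place network blobs plus the three artifact sources.

    Returns ``(source_maps, labels)`` where maps are continuous in [0, 1].
    Network maps are smoothed blobs in the brain interior with pairwise
    support overlap below 20% of either support; the first network is a
    bilateral (x-mirrored) pair.  Deterministic given ``seed``.
    """
    if n_networks < 2:
        raise ValueError("need at least 2 networks")
    if n_networks > len(_NETWORK_SLOTS):
        raise PlacementError(
            f"only {len(_NETWORK_SLOTS)} network slots available, "
            f"asked for {n_networks}"
        )
    center, semi = brain_geometry(grid_shape)
    gx, gy, gz = grid_shape
    rx, ry, rz = (min(a, b) for a, b in zip(grid_shape, _RADII_REF_GRID))
    radii = (0.115 * rx, 0.115 * ry, 0.16 * rz)
    if min(radii) < 1.0 or min(grid_shape) < 8:
        raise PlacementError(
            f"grid {grid_shape} too small to place {n_networks} networks "
            f"(blob radii {tuple(round(r, 2) for r in radii)})"
        )
    if masks is None:
        masks = make_masks(grid_shape)
    brain = masks["brain"].data

    rng = np.random.default_rng(seed)
    for attempt in range(max_retries):
        maps = []
        ok = True
        for slot in range(n_networks):
            (fx, fy, fz), bilateral = _NETWORK_SLOTS[slot]
            jit = rng.uniform(-1.0, 1.0, size=3) * np.array([1.0, 1.0, 0.5])
            if bilateral:
                c = np.array(center) + np.array([fx, fy, fz]) * np.array(semi)
                c2 = np.array(center) + np.array([-fx, fy, fz]) * np.array(semi)
                r = tuple(0.85 * x for x in radii)
                m = np.maximum(
                    _blob(grid_shape, c + jit, r, brain),
                    _blob(grid_shape, c2 + jit * np.array([-1, 1, 1]), r, brain),
                )
            else:
                c = np.array(center) + np.array([fx, fy, fz]) * np.array(semi)
                m = _blob(grid_shape, c + jit, radii, brain)
            maps.append(m)
        supports = [_support(m) for m in maps]
        for i in range(n_networks):
            for j in range(i + 1, n_networks):
                inter = int((supports[i] & supports[j]).sum())
                lim = 0.2 * min(supports[i].sum(), supports[j].sum())
                if inter >= lim:
                    ok = False
        if ok:
            break
    else:
        raise PlacementError(
            f"could not satisfy the 20% overlap constraint in {max_retries} tries"
        )

    labels = [NETWORK] * n_networks

    # artifact sources.  The ring is modulated by a smooth random field:
    # residual-motion rings are strongest where local gradients are, not
    # uniform, and a uniform dense rim would be a near-binary sub-Gaussian
    # source that spatial ICA cannot isolate.
    rim = inplane_ring_mask(brain, width=1)
    field = ndimage.gaussian_filter(rng.standard_normal(grid_shape), sigma=1.5)
    ring = np.zeros(grid_shape)
    # signed smooth modulation along the rim: residual-motion rings show
    # complementary positive and negative arcs, and a signed sparse
    # source is identifiable by spatial ICA where a uniform rim is not
    ring[rim] = field[rim] / np.abs(field[rim]).max()
    maps.append(ring)
    labels.append(RING)

    maps.append(masks["vessel"].data.astype(float))
    labels.append(VESSEL)

    sus_center = (center[0], center[1] + 0.72 * semi[1], center[2] + 0.05 * gz)
    sus = _blob(grid_shape, sus_center, (0.10 * rx, 0.08 * ry, 0.16 * rz), brain)
    sus[rim] = 0.0   # keep the dropout blob off the motion ring's rim
    maps.append(sus)
    labels.append(SUSCEPTIBILITY)

    return np.stack(maps), labels


#: relative source amplitudes: artifact sources are the strongest
#: components in real resting-state data
SOURCE_AMPLITUDE = {NETWORK: 1.0, RING: 2.0, VESSEL: 1.5, SUSCEPTIBILITY: 1.5}


def make_timecourses(n_volumes, tr_s, band_hz, n_sources, seed,
                     max_corr=0.3, max_retries=50) -> np.ndarray:
    """Band-limited, unit-variance, weakly correlated source time courses.

    Gaussian white noise is masked to the band in the FFT domain, inverse
    transformed and standardised; columns whose pairwise correlation
    exceeds ``max_corr`` in absolute value are resampled.
    """
    if n_volumes < 16:
        raise ValueError(f"need at least 16 volumes, got {n_volumes}")
    low, high = band_hz
    nyq = 1.0 / (2.0 * tr_s)
    if not (0.0 < low < high <= nyq):
        raise BandError(f"band {band_hz} infeasible at TR {tr_s} s (Nyquist {nyq:.4f})")
    freqs = np.fft.rfftfreq(n_volumes, d=tr_s)
    in_band = (freqs >= low) & (freqs <= high)
    if not in_band.any():
        raise BandError(f"band {band_hz} contains no DFT bin at n={n_volumes}")

    rng = np.random.default_rng(seed)

    def draw(n_cols):
        white = rng.standard_normal((n_volumes, n_cols))
        spec = np.fft.rfft(white, axis=0)
        spec[~in_band] = 0.0
        ts = np.fft.irfft(spec, n=n_volumes, axis=0)
        ts -= ts.mean(axis=0)
        ts /= ts.std(axis=0)
        return ts

    tc = draw(n_sources)
    for _ in range(max_retries):
        r = np.corrcoef(tc.T)
        np.fill_diagonal(r, 0.0)
        bad = np.unique(np.nonzero(np.abs(r) >= max_corr)[0])
        if bad.size == 0:
            return tc
        tc[:, bad] = draw(bad.size)
    # short runs have few in-band DFT bins, so resampling alone may never
    # succeed; symmetric decorrelation is band-preserving (linear
    # combinations of band-limited series stay band-limited)
    if 2 * int(in_band.sum()) < n_sources:
        raise BandError(
            f"band {band_hz} at n={n_volumes} has too few DFT bins for "
            f"{n_sources} decorrelated sources"
        )
    cov = np.cov(tc.T)
    evals, evecs = np.linalg.eigh(cov)
    white = evecs @ np.diag(evals**-0.5) @ evecs.T
    tc = tc @ white.T
    tc -= tc.mean(axis=0)
    tc /= tc.std(axis=0)
    return tc


def _motion_walk(n_volumes, rng, step_mm=0.022, step_deg=0.015, bound=1.5):
    """Bounded random-walk realignment parameters (reflective at ±bound)."""
    steps = np.empty((n_volumes, 6))
    steps[:, :3] = rng.normal(0.0, step_mm, size=(n_volumes, 3))
    steps[:, 3:] = rng.normal(0.0, step_deg, size=(n_volumes, 3))
    walk = np.cumsum(steps, axis=0)
    # reflect into [-bound, bound]
    walk = np.abs((walk + bound) % (4 * bound) - 2 * bound) - bound
    return walk


def generate_study(
    n_subjects: int = 22,
    runs_per_subject: int = 2,
    n_volumes: int = 139,
    snr: float = 1.0,
    seed: int = 11,
    n_networks: int = 4,
    include_artifacts: bool = True,
    grid_shape=DEFAULT_GRID,
    config: StudyConfig | None = None,
    baseline: float = 100.0,
    subject_jitter_vox: float = 0.0,
    structured_noise_fraction: float = 0.15,
    n_structured: int = 10,
    noise_band_hz: tuple = (0.008, 0.105),
) -> Study:
    """Simulate a full multi-subject study with ground truth attached.

    Each run is baseline + sum of (source map x band-limited time course x
    per-subject lognormal gain) + a shared broadband nuisance signal in
    WM/CSF voxels + linear drift + Gaussian noise.  The noise sd is set so
    that the mean signal sd over source-support voxels divided by the
    noise sd equals ``snr``.

    Between-subject spatial variability — without which group inference
    on back-projected maps degenerates — is modelled by displacing every
    source map by a per-(subject, source) random shift of sd
    ``subject_jitter_vox`` voxels (halved through-plane), fixed across a
    subject's runs like anatomy.  The noise budget is split between white
    noise and ``n_structured`` random smooth spatial patterns with
    band-limited time courses (``structured_noise_fraction`` of the noise
    variance) — the spatially correlated residue (physiology, residual
    motion) that makes single-subject estimates genuinely noisy in real
    data.  With ``n_networks=0`` and ``include_artifacts=False`` a
    pure-noise (null) study is produced.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    cfg = config or StudyConfig(rng_seed=seed)
    masks = make_masks(grid_shape)
    affine = masks["brain"].affine
    brain = masks["brain"].data
    flat_brain = brain.reshape(-1)
    wmcsf = (masks["white"].data | masks["csf"].data).reshape(-1)[flat_brain]

    if n_networks > 0:
        src_maps, labels = make_sources(grid_shape, n_networks, seed, masks)
        if not include_artifacts:
            keep = [i for i, l in enumerate(labels) if l == NETWORK]
            src_maps, labels = src_maps[keep], [labels[i] for i in keep]
    elif include_artifacts:
        src_maps, labels = make_sources(grid_shape, 2, seed, masks)
        keep = [i for i, l in enumerate(labels) if l != NETWORK]
        src_maps, labels = src_maps[keep], [labels[i] for i in keep]
    else:
        src_maps = np.zeros((0, *grid_shape))
        labels = []
    n_sources = src_maps.shape[0]

    master = np.random.default_rng(seed)
    truth = PhantomTruth(
        source_maps=src_maps, labels=labels, timecourses={},
        subject_gains={}, noise_sigma={}, grid_shape=tuple(grid_shape),
        affine=affine,
    )

    runs: list[SubjectRun] = []
    vb = int(flat_brain.sum())
    ramp = np.linspace(0.0, 1.0, n_volumes)
    amps = np.array([SOURCE_AMPLITUDE[l] for l in labels]) if n_sources else np.empty(0)
    for s in range(n_subjects):
        subject_id = f"sub{s + 1:02d}"
        gains = amps * np.exp(master.normal(0.0, 0.2, size=n_sources))
        truth.subject_gains[subject_id] = gains
        # subject-specific functional topography: network maps shifted by
        # a random sub-voxel offset, constant across the subject's runs.
        # Artifact sources stay fixed — edge rings, vessels and
        # susceptibility dropout are locked to template geometry.
        subj_maps = np.empty((n_sources, vb))
        for si in range(n_sources):
            if labels[si] == NETWORK:
                shift = master.normal(0.0, subject_jitter_vox, size=3)
                shift[2] *= 0.5
                shifted = ndimage.shift(src_maps[si], shift, order=1,
                                        mode="constant", cval=0.0)
                shifted[~brain] = 0.0
                subj_maps[si] = shifted.reshape(-1)[flat_brain]
            else:
                subj_maps[si] = src_maps[si].reshape(-1)[flat_brain]
        # noise is calibrated against source cores (|map| > 0.5); the
        # faint support tail would otherwise dilute the reference level
        subj_core = np.abs(subj_maps) > 0.5
        for run_idx in range(1, runs_per_subject + 1):
            rng = np.random.default_rng(
                master.integers(0, 2**31 - 1)
            )
            tc = (
                make_timecourses(
                    n_volumes, cfg.tr_s, cfg.band_hz, n_sources,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                if n_sources
                else np.zeros((n_volumes, 0))
            )
            truth.timecourses[(subject_id, run_idx)] = tc

            if n_sources:
                amp = np.sqrt(((subj_maps * gains[:, None]) ** 2).sum(axis=0))
                # calibrate noise against the network sources (the signal
                # of interest); artifact sources are stronger by design
                net = [i for i, l in enumerate(labels) if l == NETWORK]
                ref = subj_core[net].any(axis=0) if net else subj_core.any(axis=0)
                sigma = float(amp[ref].mean()) / snr
            else:
                sigma = 1.0
            truth.noise_sigma[(subject_id, run_idx)] = sigma

            data_b = np.full((vb, n_volumes), baseline, dtype=np.float64)
            if n_sources:
                data_b += (subj_maps * gains[:, None]).T @ tc.T
            nuis = rng.standard_normal(n_volumes)
            nuis = (nuis - nuis.mean()) / nuis.std()
            data_b[wmcsf] += 0.8 * sigma * nuis
            slope = rng.uniform(-0.005, 0.005)
            data_b += baseline * slope * ramp
            # low-frequency-dominated voxel noise, as in BOLD: white noise
            # masked to noise_band_hz and rescaled to unit variance
            w = np.sqrt(1.0 - structured_noise_fraction)
            white = rng.standard_normal((vb, n_volumes))
            freqs = np.fft.rfftfreq(n_volumes, d=cfg.tr_s)
            keep = (freqs >= noise_band_hz[0]) & (freqs <= noise_band_hz[1])
            spec = np.fft.rfft(white, axis=1)
            spec[:, ~keep] = 0.0
            colored = np.fft.irfft(spec, n=n_volumes, axis=1)
            colored /= colored.std(axis=1, keepdims=True)
            data_b += w * sigma * colored
            if structured_noise_fraction > 0 and n_structured > 0:
                sn_maps = np.empty((n_structured, vb))
                for q in range(n_structured):
                    f = ndimage.gaussian_filter(
                        rng.standard_normal(grid_shape), sigma=1.5
                    )
                    f = f.reshape(-1)[flat_brain]
                    sn_maps[q] = f / f.std()
                sn_tc = make_timecourses(
                    n_volumes, cfg.tr_s, cfg.band_hz, n_structured,
                    seed=int(rng.integers(0, 2**31 - 1)), max_corr=1.1,
                )
                scale = sigma * np.sqrt(structured_noise_fraction / n_structured)
                data_b += scale * (sn_maps.T @ sn_tc.T)

            full = np.zeros((flat_brain.size, n_volumes), dtype=np.float32)
            full[flat_brain] = data_b
            vol = Volume4D(
                data=full.reshape(*grid_shape, n_volumes),
                affine=affine, tr_s=cfg.tr_s,
            )
            motion = MotionTrace(params=_motion_walk(n_volumes, rng))
            runs.append(
                SubjectRun(
                    subject_id=subject_id, run_index=run_idx,
                    volume=vol, motion=motion,
                )
            )
    return Study(runs=runs, masks=masks, config=cfg, truth=truth)


def write_study(study: Study, outdir: str | Path) -> Path:
    """Write a study to disk in the manifest layout core_io reads back.

    Returns the manifest path.  Ground truth (when present) is saved as a
    4D source-map NIfTI plus per-run time-course TSVs under ``truth/``.
    """
    outdir = Path(outdir)
    (outdir / "func").mkdir(parents=True, exist_ok=True)
    (outdir / "motion").mkdir(exist_ok=True)
    (outdir / "masks").mkdir(exist_ok=True)

    entries = []
    for r in study.runs:
        stem = f"{r.subject_id}_run{r.run_index}"
        save_volume(r.volume, outdir / "func" / f"{stem}.nii.gz")
        save_motion(r.motion, outdir / "motion" / f"{stem}.txt")
        entries.append(
            {"subject": r.subject_id, "run": r.run_index,
             "bold": f"func/{stem}.nii.gz", "motion": f"motion/{stem}.txt"}
        )
    mask_entries = {}
    for role, m in study.masks.items():
        save_mask(m, outdir / "masks" / f"{role}.nii.gz")
        mask_entries[role] = f"masks/{role}.nii.gz"

    from dataclasses import asdict

    cfg = asdict(study.config)
    cfg["band_hz"] = list(study.config.band_hz)
    cfg["model_orders"] = list(study.config.model_orders)
    manifest = {"config": cfg, "masks": mask_entries, "runs": entries}
    mpath = outdir / "manifest.yaml"
    mpath.write_text(yaml.safe_dump(manifest, sort_keys=False))

    if study.truth is not None:
        import nibabel as nib
        import pandas as pd

        tdir = outdir / "truth"
        tdir.mkdir(exist_ok=True)
        t = study.truth
        img = nib.Nifti1Image(
            np.moveaxis(t.source_maps, 0, -1).astype(np.float32), t.affine
        )
        nib.save(img, str(tdir / "source_maps.nii.gz"))
        (tdir / "labels.txt").write_text("\n".join(t.labels) + "\n")
        for (sid, ridx), tc in t.timecourses.items():
            pd.DataFrame(tc).to_csv(
                tdir / f"{sid}_run{ridx}_timecourses.tsv",
                sep="\t", index=False,
            )
    return mpath
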