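"""Rule-based artifact screening of thresholded components.

Three codified rules, each yielding a flag plus a scalar evidence value:

* susceptibility — fraction of cluster centres inside the susceptibility
  boundary region (the anterior area prone to dropout); flag when the
  majority (> 0.5) of clusters sit there,
* motion ring — fraction of suprathreshold voxels (both polarities
  pooled) inside a rim at the brain edge; flag when > 0.6,
* vessel — Dice overlap between the component mask and a vessel mask;
  flag when > 0.3.

Screening is read-only: it never alters maps or clusters.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core_io import MaskVolume
from .maps_stats import ThresholdedComponent
from .reproducibility import dsc

SUSCEPTIBILITY = "susceptibility"
MOTION_RING = "motion_ring"
VESSEL = "vessel"


@dataclass
class ComponentFlag:
    """Screening verdict for one component."""

    component_id: int
    flags: set = field(default_factory=set)
    evidence: dict = field(default_factory=dict)

    @property
    def verdict(self) -> str:
        return "artifact" if self.flags else "neural_candidate"


def _dominant_polarity(component: ThresholdedComponent) -> str:
    """The polarity carrying most of the component's surviving extent.

    A component's sign is canonicalised per decomposition, so the side
    holding its main structure can be either tail; the dominant side is
    the one with more surviving voxels.
    """
    return ("positive" if component.pos_mask.sum() >= component.neg_mask.sum()
            else "negative")


def susceptibility_flag(component: ThresholdedComponent,
                        boundary: MaskVolume | np.ndarray,
                        threshold: float = 0.5,
                        polarity: str = "auto"):
    """Size-weighted fraction of surviving-cluster extent whose cluster
    centres lie inside the boundary region.

    With ``polarity="auto"`` the positive and negative clusters are
    scored separately and the larger fraction is taken — an artifact can
    occupy either tail of a sign-canonicalised map.
    """
    region = boundary.data if isinstance(boundary, MaskVolume) else np.asarray(boundary, bool)
    # centre of statistical mass: |t|-weighted centre is stable under the
    # choice of display threshold (clusters were inspected "with multiple
    # thresholds"), where the binary-extent centre of a cluster fused with
    # low-t surroundings is not
    tvals = np.abs(component.tmap.t_values) if component.tmap is not None else None
    t3d = None
    if tvals is not None:
        t3d = np.zeros(component.mask3d.shape)
        finite = np.where(np.isfinite(tvals), tvals, 0.0)
        t3d[component.mask3d] = finite

    def _centre(c):
        if t3d is None:
            return c.center_of_mass
        w = t3d[tuple(c.voxels.T)]
        if w.sum() == 0:
            return c.center_of_mass
        return tuple((c.voxels * w[:, None]).sum(axis=0) / w.sum())

    def _frac(pol):
        clusters = [c for c in component.surviving_clusters
                    if pol == "both" or c.polarity == pol]
        if not clusters:
            return 0.0
        inside = 0
        for c in clusters:
            idx = tuple(
                int(np.clip(round(x), 0, s - 1))
                for x, s in zip(_centre(c), region.shape)
            )
            if region[idx]:
                inside += c.size
        # size-weighted majority: "predominantly" should not let a
        # few-voxel satellite cluster out-vote the main cluster
        return inside / sum(c.size for c in clusters)

    if polarity == "auto":
        frac = _frac(_dominant_polarity(component))
    else:
        frac = _frac(polarity)
    return frac > threshold, frac


def edge_ring_score(component: ThresholdedComponent,
                    brain_mask: MaskVolume | np.ndarray,
                    rim_width_voxels: int = 2,
                    threshold: float = 0.6):
    """Fraction of suprathreshold voxels (pooled polarities) in the brain rim."""
    brain = brain_mask.data if isinstance(brain_mask, MaskVolume) else np.asarray(brain_mask, bool)
    rim = brain & ~ndimage.binary_erosion(brain, iterations=rim_width_voxels)
    mask = component.voxel_mask
    total = int(mask.sum())
    if total == 0:
        return False, 0.0
    frac = int((mask & rim).sum()) / total
    return frac > threshold, frac


def vessel_flag(component: ThresholdedComponent,
                vessel_mask: MaskVolume | np.ndarray | None,
                threshold: float = 0.3,
                polarity: str = "auto"):
    """Dice overlap between the component mask and the vessel mask.

    With ``polarity="auto"`` the positive- and negative-polarity masks
    are scored separately and the larger Dice is taken; pooling the two
    would dilute the overlap with the opposite tail's residue.
    """
    if vessel_mask is None:
        return False, float("nan")
    vm = vessel_mask.data if isinstance(vessel_mask, MaskVolume) else np.asarray(vessel_mask, bool)
    b = set(map(tuple, np.argwhere(vm)))

    def _dice(mask):
        a = set(map(tuple, np.argwhere(mask)))
        return dsc(a, b) if a else 0.0

    if polarity == "auto":
        d = _dice(component.pos_mask
                  if _dominant_polarity(component) == "positive"
                  else component.neg_mask)
    elif polarity == "both":
        d = _dice(component.voxel_mask)
    else:
        d = _dice(component.pos_mask if polarity == "positive" else component.neg_mask)
    return d > threshold, d


def screen_component(component: ThresholdedComponent,
                     masks: dict[str, MaskVolume],
                     rim_width_voxels: int = 2) -> ComponentFlag:
    """Apply all three rules to one component."""
    flag = ComponentFlag(component_id=component.component_id)

    if "susceptibility_boundary" in masks:
        hit, ev = susceptibility_flag(component, masks["susceptibility_boundary"])
        flag.evidence[SUSCEPTIBILITY] = ev
        if hit:
            flag.flags.add(SUSCEPTIBILITY)

    hit, ev = edge_ring_score(component, masks["brain"], rim_width_voxels)
    flag.evidence[MOTION_RING] = ev
    if hit:
        flag.flags.add(MOTION_RING)

    hit, ev = vessel_flag(component, masks.get("vessel"))
    flag.evidence[VESSEL] = ev
    if hit:
        flag.flags.add(VESSEL)
    return flag


def screen_components(components: list[ThresholdedComponent],
                      masks: dict[str, MaskVolume],
                      rim_width_voxels: int = 2) -> list[ComponentFlag]:
    return [screen_component(c, masks, rim_width_voxels) for c in components]


def verdict_table(flags: list[ComponentFlag]) -> pd.DataFrame:
    """TSV-ready verdict table (component, flags, evidence, verdict)."""
    rows = []
    for f in flags:
        row = {"component": f.component_id,
               "flags": ",".join(sorted(f.flags)) or "-",
               "verdict": f.verdict}
        for k, v in f.evidence.items():
            row[f"evidence_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
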