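"""End-to-end orchestration.

Ties the stages together in memory: simulate (or load) a study,
preprocess every run, decompose with group ICA, threshold and screen
components, and run the split-half reproducibility analysis.  The
evaluation helpers compare the result against a phantom's ground truth
and are the basis of both the recovery test-suite and the CLI's report.
"""
from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import phantom as ph
from .config import StudyConfig
from .core_io import Study
from .gica import GroupDecomposition, run_gica
from .maps_stats import ThresholdedComponent, threshold_components
from .preprocess import PreprocessedRun, preprocess_study
from .reproducibility import (
    binarize_component,
    cross_subset_consistency,
    dsc_matrix,
    match_and_label,
    split_half,
)
from .screen import ComponentFlag, screen_components

#: labels given to reference components of a decomposition, in variance order
COMPONENT_LETTERS = list(string.ascii_uppercase)


def subject_map_stack(decomp: GroupDecomposition) -> np.ndarray:
    """(k, n_subjects, V) stack of per-subject back-projected maps."""
    sids = sorted(decomp.subject_maps)
    arr = np.stack([decomp.subject_maps[s] for s in sids])  # (n, k, V)
    return np.swapaxes(arr, 0, 1)


def spatial_correlations(est_maps: np.ndarray, truth_maps: np.ndarray) -> np.ndarray:
    """|Pearson r| between every truth map (rows) and estimated map (cols)."""
    def _z(m):
        m = m - m.mean(axis=1, keepdims=True)
        sd = m.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return m / sd
    t = _z(np.asarray(truth_maps, float))
    e = _z(np.asarray(est_maps, float))
    return np.abs(t @ e.T) / t.shape[1]


def component_tmaps(decomp: GroupDecomposition) -> np.ndarray:
    """(k, V) one-sample t-maps over subjects — the component maps as the
    field reports them."""
    stack = subject_map_stack(decomp)
    mean = stack.mean(axis=1)
    sd = stack.std(axis=1, ddof=1)
    sd[sd == 0] = 1.0
    return mean / (sd / np.sqrt(stack.shape[1]))


def match_components_to_truth(decomp: GroupDecomposition,
                              truth: ph.PhantomTruth,
                              brain_mask: np.ndarray) -> pd.DataFrame:
    """Best-matching estimated component for every planted source.

    Components are represented by their group t-maps (the standard
    reporting map for a group decomposition) and matched by maximum
    absolute spatial correlation.
    """
    flat = truth.source_maps.reshape(truth.n_sources, -1)[:, brain_mask.ravel()]
    r = spatial_correlations(component_tmaps(decomp), flat)
    rows = []
    for s in range(truth.n_sources):
        c = int(np.argmax(r[s]))
        rows.append({"source": s, "label": truth.labels[s],
                     "component": c, "abs_corr": float(r[s, c])})
    return pd.DataFrame(rows)


@dataclass
class StudyResult:
    """Everything one full pipeline pass produces."""

    study: Study
    preprocessed: list[PreprocessedRun]
    decomposition: GroupDecomposition
    components: list[ThresholdedComponent]
    flags: list[ComponentFlag]
    split_assignments: tuple | None = None
    consistency: pd.DataFrame | None = None
    split_components: tuple | None = None


def analyze_study(study: Study, model_order: int, seed: int | None = None,
                  with_splits: bool = True,
                  n_permutations: int | None = None) -> StudyResult:
    """Run preprocess -> group ICA -> dual-FDR maps -> screening ->
    (optionally) split-half reproducibility on a loaded or simulated study."""
    cfg = study.config
    seed = cfg.rng_seed if seed is None else seed
    n_perm = cfg.n_permutations if n_permutations is None else n_permutations
    brain = study.masks["brain"].data

    pre = preprocess_study(study)
    decomp = run_gica(pre, model_order, seed=seed)
    comps = threshold_components(
        subject_map_stack(decomp), brain,
        q_voxel=cfg.q_voxel, q_cluster=cfg.q_cluster,
        n_permutations=n_perm, seed=seed,
    )
    flags = screen_components(comps, study.masks)

    result = StudyResult(
        study=study, preprocessed=pre, decomposition=decomp,
        components=comps, flags=flags,
    )
    if with_splits:
        result = _add_splits(result, model_order, seed, n_perm)
    return result


def _add_splits(result: StudyResult, model_order: int, seed: int,
                n_perm: int) -> StudyResult:
    cfg = result.study.config
    brain = result.study.masks["brain"].data
    half1, half2 = split_half(result.preprocessed)
    d1 = run_gica(half1, model_order, seed=seed + 1)
    d2 = run_gica(half2, model_order, seed=seed + 2)
    th1 = threshold_components(
        subject_map_stack(d1), brain, q_voxel=cfg.q_voxel,
        q_cluster=cfg.q_cluster, n_permutations=n_perm, seed=seed + 101,
    )
    th2 = threshold_components(
        subject_map_stack(d2), brain, q_voxel=cfg.q_voxel,
        q_cluster=cfg.q_cluster, n_permutations=n_perm, seed=seed + 202,
    )
    # pooled polarity: component sign is not comparable across
    # independently canonicalised decompositions
    refs = {COMPONENT_LETTERS[i]: binarize_component(c, polarity="both")
            for i, c in enumerate(result.components)}
    cands1 = [binarize_component(c, polarity="both") for c in th1]
    cands2 = [binarize_component(c, polarity="both") for c in th2]
    a1 = match_and_label(dsc_matrix(refs, cands1), tau_match=cfg.tau_match)
    a2 = match_and_label(dsc_matrix(refs, cands2), tau_match=cfg.tau_match)
    cross = dsc_matrix(dict(enumerate(cands1)), cands2)
    cons = cross_subset_consistency(a1, a2, cross,
                                    tau_consistency=cfg.tau_consistency)
    result.split_assignments = (a1, a2)
    result.consistency = cons
    result.split_components = (th1, th2)
    return result


# ---------------------------------------------------------------------------
# phantom evaluation against ground truth
# ---------------------------------------------------------------------------

@dataclass
class PhantomEvaluation:
    """Ground-truth scorecard of one simulated study."""

    seed: int
    recovery: pd.DataFrame            # per-source best component + |corr|
    network_corrs: dict               # source idx -> |corr|
    network_flagged: dict             # source idx -> bool (falsely flagged)
    artifact_flagged: dict            # truth label -> bool (correctly flagged)
    network_consistency: dict         # source idx -> split-half DSC (NaN if unmatched)
    flags: list[ComponentFlag]
    consistency: pd.DataFrame
    probe_corrs: dict = field(default_factory=dict)

    @property
    def all_networks_recovered(self) -> bool:
        return all(v >= 0.8 for v in self.network_corrs.values())

    @property
    def all_artifacts_flagged(self) -> bool:
        return all(self.artifact_flagged.values())

    @property
    def no_network_flagged(self) -> bool:
        return not any(self.network_flagged.values())

    @property
    def all_networks_consistent(self) -> bool:
        return all(np.isfinite(v) and v > 0.25
                   for v in self.network_consistency.values())


_FLAG_FOR_LABEL = {
    ph.RING: "motion_ring",
    ph.VESSEL: "vessel",
    ph.SUSCEPTIBILITY: "susceptibility",
}


def evaluate_phantom_study(
    seed: int,
    n_subjects: int = 22,
    runs_per_subject: int = 2,
    n_volumes: int = 139,
    snr: float = 1.0,
    n_networks: int = 4,
    model_order: int | None = None,
    probe_model_order: int | None = None,
    n_permutations: int = 1000,
    with_splits: bool = True,
) -> PhantomEvaluation:
    """Simulate a study, run the full pipeline and score it against truth.

    The default model order is ``n_networks + 3`` (one component per
    planted network plus the three artifact sources).  When
    ``probe_model_order`` is given, an extra decomposition at that order
    is run and its truth correlations recorded (robustness probe for
    over-specified model orders).
    """
    k = model_order or (n_networks + 3)
    study = ph.generate_study(
        n_subjects=n_subjects, runs_per_subject=runs_per_subject,
        n_volumes=n_volumes, snr=snr, seed=seed, n_networks=n_networks,
    )
    res = analyze_study(study, k, seed=seed, with_splits=with_splits,
                        n_permutations=n_permutations)
    truth = study.truth
    brain = study.masks["brain"].data
    recovery = match_components_to_truth(res.decomposition, truth, brain)

    network_corrs, network_flagged, network_consistency = {}, {}, {}
    artifact_flagged = {}
    for _, row in recovery.iterrows():
        s, comp = int(row["source"]), int(row["component"])
        if row["label"] == ph.NETWORK:
            network_corrs[s] = row["abs_corr"]
            network_flagged[s] = bool(res.flags[comp].flags)
            if with_splits:
                lab = COMPONENT_LETTERS[comp]
                hit = (res.consistency["label"] == lab)
                network_consistency[s] = (
                    float(res.consistency.loc[hit, "dsc"].iloc[0])
                    if hit.any() else float("nan")
                )
        else:
            wanted = _FLAG_FOR_LABEL[row["label"]]
            artifact_flagged[row["label"]] = wanted in res.flags[comp].flags

    probe_corrs = {}
    if probe_model_order:
        d_probe = run_gica(res.preprocessed, probe_model_order, seed=seed + 7)
        rec = match_components_to_truth(d_probe, truth, brain)
        for _, row in rec.iterrows():
            if row["label"] == ph.NETWORK:
                probe_corrs[int(row["source"])] = row["abs_corr"]

    return PhantomEvaluation(
        seed=seed, recovery=recovery, network_corrs=network_corrs,
        network_flagged=network_flagged, artifact_flagged=artifact_flagged,
        network_consistency=network_consistency, flags=res.flags,
        consistency=res.consistency if with_splits else pd.DataFrame(),
        probe_corrs=probe_corrs,
    )


def evaluate_null_study(
    seed: int,
    n_subjects: int = 22,
    runs_per_subject: int = 2,
    n_volumes: int = 139,
    model_order: int = 7,
    n_permutations: int = 1000,
) -> dict:
    """Run the pipeline on a source-free (pure noise + nuisance) phantom.

    Returns the number of components with any cluster surviving the dual
    FDR thresholds — the type-I control probe.
    """
    study = ph.generate_study(
        n_subjects=n_subjects, runs_per_subject=runs_per_subject,
        n_volumes=n_volumes, snr=1.0, seed=seed,
        n_networks=0, include_artifacts=False,
    )
    res = analyze_study(study, model_order, seed=seed, with_splits=False,
                        n_permutations=n_permutations)
    n_hit = sum(1 for c in res.components if c.voxel_mask.any())
    return {"seed": seed, "n_components": model_order,
            "n_with_surviving_cluster": n_hit}
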