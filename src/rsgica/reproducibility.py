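"""Split-half reproducibility: Dice overlap, component matching and
cross-subset consistency.

The matching rule mirrors the published procedure: every candidate
component of a sub-decomposition is compared with every labelled
reference component via the Dice similarity coefficient (DSC); each
reference label claims its best-overlapping candidate, conflicts are
resolved in favour of the higher DSC (the loser re-runs its argmax among
unclaimed candidates), matches below the 0.3 threshold are rejected, and
unclaimed candidates receive fresh letters.  Consistency across the two
halves is the DSC between the same-labelled components, good when above
0.25.
"""
from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .maps_stats import ThresholdedComponent

#: reserved alphabet for unclaimed candidates
FRESH_LETTERS = ["X", "Y", "Z", "V", "W", "U", "T", "S", "R", "Q", "P"]


def binarize_component(component: ThresholdedComponent,
                       polarity: str = "positive") -> frozenset:
    """FDR-surviving voxel set of a thresholded component.

    Positive polarity by default; ``polarity="both"`` pools positive and
    negative survivors, ``"negative"`` takes the negative mask only.
    """
    if polarity == "positive":
        mask = component.pos_mask
    elif polarity == "negative":
        mask = component.neg_mask
    elif polarity == "both":
        mask = component.voxel_mask
    else:
        raise ValueError(f"unknown polarity '{polarity}'")
    return frozenset(map(tuple, np.argwhere(mask)))


def dsc(a, b) -> float:
    """Dice similarity coefficient 2|a∩b| / (|a|+|b|) of two voxel sets.

    Ranges from 0 (no overlap) to 1 (complete overlap).  Both sets empty
    is defined as 0 with a warning.
    """
    a, b = set(a), set(b)
    if not a and not b:
        warnings.warn("DSC of two empty sets defined as 0", RuntimeWarning)
        return 0.0
    return 2.0 * len(a & b) / (len(a) + len(b))


def dsc_matrix(references: dict, candidates) -> pd.DataFrame:
    """Full DSC matrix: reference labels as rows, candidates as columns."""
    if isinstance(candidates, dict):
        cand_ids = list(candidates.keys())
        cand_sets = [candidates[c] for c in cand_ids]
    else:
        cand_ids = list(range(len(candidates)))
        cand_sets = list(candidates)
    vals = [[dsc(rset, cset) for cset in cand_sets]
            for rset in references.values()]
    return pd.DataFrame(vals, index=list(references.keys()), columns=cand_ids)


@dataclass
class LabelAssignment:
    """Outcome of matching candidates against labelled references."""

    mapping: dict                 # candidate id -> label (matched or fresh)
    matched: list                 # (label, candidate id, dsc) triples
    unmatched_reference: list     # reference labels with no candidate
    fresh: dict                   # candidate id -> fresh label
    tau_match: float

    def label_of(self, candidate):
        return self.mapping[candidate]

    def candidate_of(self, label):
        for lab, cand, _ in self.matched:
            if lab == label:
                return cand
        raise KeyError(f"label {label!r} was not matched")

    @property
    def matched_labels(self) -> list:
        return [lab for lab, _, _ in self.matched]


def match_and_label(matrix: pd.DataFrame, tau_match: float = 0.3,
                    fresh_letters=None) -> LabelAssignment:
    """Assign reference labels to candidate components from a DSC matrix.

    Greedy in descending DSC: the globally best (reference, candidate)
    pair is matched first, which makes the winner of any conflict the
    higher-DSC reference and lets the loser fall back to its best
    remaining candidate.  Pairs below ``tau_match`` are never matched;
    unclaimed candidates get fresh letters (in candidate order) from a
    reserved alphabet that avoids the reference labels.
    """
    if matrix.shape[0] < 1 or matrix.shape[1] < 1:
        raise ValueError("need at least one reference and one candidate")
    vals = matrix.to_numpy(dtype=float).copy()
    refs = list(matrix.index)
    cands = list(matrix.columns)

    matched = []
    open_rows = np.ones(len(refs), dtype=bool)
    open_cols = np.ones(len(cands), dtype=bool)
    while open_rows.any() and open_cols.any():
        sub = np.where(np.outer(open_rows, open_cols), vals, -np.inf)
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] < tau_match:
            break
        matched.append((refs[i], cands[j], float(vals[i, j])))
        open_rows[i] = False
        open_cols[j] = False
    matched.sort(key=lambda t: refs.index(t[0]))

    mapping = {cand: lab for lab, cand, _ in matched}
    unmatched_ref = [r for r, open_ in zip(refs, open_rows) if open_]

    if fresh_letters is None:
        fresh_letters = [l for l in FRESH_LETTERS if l not in refs]
        fresh_letters += [l for l in string.ascii_uppercase
                          if l not in refs and l not in fresh_letters]
    fresh = {}
    it = iter(fresh_letters)
    for c, open_ in zip(cands, open_cols):
        if open_:
            label = next(it, None)
            if label is None:
                label = f"N{len(fresh)}"
            fresh[c] = label
            mapping[c] = label

    return LabelAssignment(
        mapping=mapping, matched=matched, unmatched_reference=unmatched_ref,
        fresh=fresh, tau_match=tau_match,
    )


def split_half(runs, min_subjects: int = 3):
    """Split a study's runs into first-run and second-run halves.

    Accepts a list of objects with ``subject_id``/``run_index`` (SubjectRun
    or PreprocessedRun) or a Study.  Subjects missing a run are excluded
    from that half only (with a warning).
    """
    if hasattr(runs, "runs"):
        runs = runs.runs
    half1 = [r for r in runs if r.run_index == 1]
    half2 = [r for r in runs if r.run_index == 2]
    s1 = {r.subject_id for r in half1}
    s2 = {r.subject_id for r in half2}
    if s1 != s2:
        warnings.warn(
            f"subjects present in one half only: {sorted(s1 ^ s2)}",
            RuntimeWarning,
        )
    if len(s1) < min_subjects or len(s2) < min_subjects:
        raise ValueError(
            f"split-half needs at least {min_subjects} subjects per half "
            f"(got {len(s1)} and {len(s2)})"
        )
    return half1, half2


def cross_subset_consistency(assign1: LabelAssignment,
                             assign2: LabelAssignment,
                             cross_dsc: pd.DataFrame,
                             tau_consistency: float = 0.25) -> pd.DataFrame:
    """Consistency of same-labelled components across the two halves.

    ``cross_dsc`` is the DSC matrix between subset-1 candidates (rows)
    and subset-2 candidates (columns).  For every label matched in both
    halves the DSC between the two components carrying it is reported,
    with verdict ``good`` iff it exceeds ``tau_consistency``.  Labels
    matched in at most one half are absent from the table.
    """
    labels = [l for l in assign1.matched_labels if l in assign2.matched_labels]
    rows = []
    for lab in labels:
        c1 = assign1.candidate_of(lab)
        c2 = assign2.candidate_of(lab)
        val = float(cross_dsc.loc[c1, c2])
        rows.append({
            "label": lab, "candidate_1": c1, "candidate_2": c2,
            "dsc": val, "good": val > tau_consistency,
        })
    return pd.DataFrame(rows, columns=["label", "candidate_1", "candidate_2",
                                       "dsc", "good"])
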