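"""Bundled worked-example data.

Three Dice-similarity matrices from a published split-half
reproducibility analysis of a 22-dog awake resting-state group ICA
(model order 15): the DSC matrices used to label the components of each
half against the full decomposition's 15 reference networks A-O, and the
cross-half matrix between the two labelled sub-decompositions.  They
drive the worked example for the match-and-label algorithm: replaying
the labelling rules on them reproduces the published matched structure
(14 labels matched in half 1 with O unmatched; E, M and O unmatched in
half 2) and the cross-run consistency values, including the two poorly
reproducible networks B (0.15) and F (0.16).
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .reproducibility import cross_subset_consistency, match_and_label


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("rsgica.data").joinpath(name)
    with ref.open("r") as fh:
        return pd.read_csv(fh, sep="\t", index_col=0)


def splithalf_subset1_dsc() -> pd.DataFrame:
    """DSC of reference networks A-O (rows) vs first-run half components."""
    return _load("splithalf_subset1_dsc.tsv")


def splithalf_subset2_dsc() -> pd.DataFrame:
    """DSC of reference networks A-O (rows) vs second-run half components."""
    return _load("splithalf_subset2_dsc.tsv")


def splithalf_cross_dsc() -> pd.DataFrame:
    """DSC between the labelled components of the two halves."""
    return _load("splithalf_cross_dsc.tsv")


def splithalf_example(tau_match: float = 0.3, tau_consistency: float = 0.25):
    """Replay the match-and-label worked example end to end.

    Returns ``(assignment_1, assignment_2, consistency_table)``.
    """
    a1 = match_and_label(splithalf_subset1_dsc(), tau_match=tau_match)
    a2 = match_and_label(splithalf_subset2_dsc(), tau_match=tau_match)
    table = cross_subset_consistency(
        a1, a2, splithalf_cross_dsc(), tau_consistency=tau_consistency
    )
    return a1, a2, table
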