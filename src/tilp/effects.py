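"""Quantitative treatment-effect readouts.

A compound's predicted effect is summarized by four cell-function scores,
each the signed sum of the ternary states of its upstream transcription
factors (an OR-gate readout: the function moves if at least one positive
TF moves with it or one negative TF moves against it):

    cell_cycle    = RB + PLK1
    dna_repair    = P21 + RRM2
    cell_survival = NFKB - BAD + BCL2
    cell_growth   = pGSK3 + p70S6K + cMYC + cJUN

Two compounds are compared by the Pearson correlation of their outcome
vectors (similarity score), and two inferred topologies by the fraction of
reference edges they share.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .datio import TernaryProfile
from .netio import SignalingNetwork

#: canonical output definitions of the packaged breast-cancer map
DEFAULT_OUTPUT_DEFINITIONS: dict[str, dict[str, int]] = {
    "CellCycle": {"RB": 1, "PLK1": 1},
    "DNARepair": {"P21": 1, "RRM2": 1},
    "CellSurvival": {"NFKB": 1, "BAD": -1, "BCL2": 1},
    "CellGrowth": {"pGSK3": 1, "p70S6K": 1, "cMYC": 1, "cJUN": 1},
}

_CANONICAL_ORDER = ("CellCycle", "DNARepair", "CellSurvival", "CellGrowth")


@dataclass(frozen=True)
class OutcomeVector:
    """Four cell-function scores; bounds follow from the TF counts."""

    cell_cycle: int
    dna_repair: int
    cell_survival: int
    cell_growth: int

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.cell_cycle, self.dna_repair, self.cell_survival, self.cell_growth],
            dtype=float,
        )

    def as_list(self) -> list[int]:
        return [self.cell_cycle, self.dna_repair, self.cell_survival, self.cell_growth]


def compute_output_vector(
    tf_states: Mapping[str, int],
    output_definitions: Mapping[str, Mapping[str, int]] | None = None,
) -> OutcomeVector:
    """Evaluate the four output equations from TF ternary states.

    ``output_definitions`` maps output name -> {TF: +/-1 coefficient};
    defaults to the packaged breast-cancer map definitions.
    """
    defs = output_definitions or DEFAULT_OUTPUT_DEFINITIONS
    if set(defs) != set(_CANONICAL_ORDER):
        raise ValueError(
            f"output definitions must name exactly {_CANONICAL_ORDER}, got {sorted(defs)}"
        )
    scores = {}
    for name in _CANONICAL_ORDER:
        total = 0
        for tf, coef in defs[name].items():
            if tf not in tf_states:
                raise KeyError(f"missing TF state for {tf!r} (output {name})")
            total += coef * int(tf_states[tf])
        scores[name] = total
    return OutcomeVector(
        cell_cycle=scores["CellCycle"],
        dna_repair=scores["DNARepair"],
        cell_survival=scores["CellSurvival"],
        cell_growth=scores["CellGrowth"],
    )


def similarity_score(t_a, t_c) -> float:
    """Pearson correlation of two outcome vectors, in [-1, 1].

    Zero-variance vectors have no defined correlation and raise.
    """
    a = t_a.as_array() if isinstance(t_a, OutcomeVector) else np.asarray(t_a, float)
    c = t_c.as_array() if isinstance(t_c, OutcomeVector) else np.asarray(t_c, float)
    if a.shape != c.shape:
        raise ValueError("outcome vectors must have equal length")
    if np.ptp(a) == 0 or np.ptp(c) == 0:
        raise ValueError("similarity undefined for a zero-variance outcome vector")
    return float(np.corrcoef(a, c)[0, 1])


def _edge_keys(network: SignalingNetwork) -> set[tuple[str, str, int]]:
    return {e.key for e in network.edges}


def topology_similarity(network_a: SignalingNetwork, reference: SignalingNetwork) -> float:
    """Fraction of the reference network's edges present in ``network_a``."""
    ref = _edge_keys(reference)
    if not ref:
        raise ValueError("reference network has no edges")
    return len(_edge_keys(network_a) & ref) / len(ref)


def fitting_precision(
    predicted_states: Mapping[tuple[str, str], int] | pd.DataFrame,
    observed: TernaryProfile,
) -> float:
    """Exact-match fraction over observed, non-missing (protein, condition)
    pairs whose protein has a predicted state."""
    if isinstance(predicted_states, pd.DataFrame):
        pred = {
            (j, k): int(predicted_states.at[j, k])
            for j in predicted_states.index
            for k in predicted_states.columns
            if not pd.isna(predicted_states.at[j, k])
        }
    else:
        pred = dict(predicted_states)
    total = 0
    matched = 0
    for j, k, m in observed.observed_pairs():
        if (j, k) not in pred:
            continue
        total += 1
        if pred[(j, k)] == m:
            matched += 1
    if total == 0:
        raise ValueError("no observed, non-missing pairs to score")
    return matched / total


def pairwise_similarity(outcomes: Mapping[str, OutcomeVector]) -> pd.DataFrame:
    """Similarity-score matrix over a set of named outcome vectors."""
    names = list(outcomes)
    mat = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    for i, na in enumerate(names):
        for nb in names[i:]:
            try:
                s = similarity_score(outcomes[na], outcomes[nb])
            except ValueError:
                s = np.nan
            mat.at[na, nb] = s
            mat.at[nb, na] = s
    return mat
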