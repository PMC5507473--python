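"""Ensemble aggregation: rotamer probabilities -> specificity profile.

Converged per-backbone rotamer probabilities are collapsed to amino-acid
probabilities with a rotamer-count correction (amino acids with many
rotamers in the library would otherwise be artificially inflated), the
backbones of a flexible-backbone ensemble are Boltzmann-weighted per
position from their amino-acid energy sums, and the weighted average is
the predicted specificity profile.  An optional background profile divides
out generic compositional bias.

The backbone weight W is indexed by (backbone, position): each position
weighs the M backbones separately, and each position's weights sum to 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .interaction_model import (
    N_AA,
    InteractionGraph,
    SpecificityProfile,
    ValidationError,
)
from .scmf import MFParameters, MFState, run_scmf

__all__ = [
    "EnsembleAggregate",
    "PredictionResult",
    "aa_probabilities",
    "backbone_aa_energies",
    "backbone_weights",
    "combine_backbones",
    "enrich_over_background",
    "predict_specificity",
]


@dataclass
class EnsembleAggregate:
    """Per-backbone amino-acid tables and the Boltzmann backbone weights.

    ``aa_probs`` and ``aa_energies`` have shape (M, N, 20); ``weights`` has
    shape (M, N) and each position's column over backbones sums to 1.
    """

    aa_probs: np.ndarray
    aa_energies: np.ndarray
    weights: np.ndarray
    position_labels: list[str] = field(default_factory=list)

    @property
    def n_backbones(self) -> int:
        return self.aa_probs.shape[0]


def _grouped(values: np.ndarray, aa_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sum `values` by amino-acid index; also return rotamer counts per aa."""
    sums = np.zeros(N_AA)
    np.add.at(sums, aa_idx, values)
    counts = np.bincount(aa_idx, minlength=N_AA).astype(float)
    return sums, counts


def aa_probabilities(
    state: MFState, graph: InteractionGraph, gamma: float
) -> np.ndarray:
    """Collapse rotamer probabilities to an N x 20 amino-acid table.

    For each position, the probability of amino acid ``aa`` is the sum of
    its rotamers' probabilities divided by ``K_aa**gamma`` (K_aa = rotamer
    count of that amino acid there), renormalised over the amino acids
    present.  ``gamma = 0`` sums probabilities outright (many-rotamer amino
    acids inflate), ``gamma = 1`` averages them (many-rotamer amino acids
    deflate); 0.8 is a practical compromise.  Amino acids with no rotamers
    at a position get probability exactly 0.
    """
    if not 0 <= gamma <= 1:
        raise ValidationError("gamma must be in [0, 1]")
    out = np.zeros((graph.n_positions, N_AA))
    for i, aa_idx in enumerate(graph.aa_index_arrays()):
        sums, counts = _grouped(state.P[i], aa_idx)
        present = counts > 0
        out[i, present] = sums[present] / counts[present] ** gamma
        out[i] /= out[i].sum()
    return out


def backbone_aa_energies(
    state: MFState, graph: InteractionGraph, gamma: float
) -> np.ndarray:
    """N x 20 table of probability-weighted amino-acid mean-field energies.

    Entry (i, aa) is ``sum_r E(i,r) * P(i,r) / K_aa**gamma`` over that amino
    acid's rotamers; absent amino acids contribute 0 to downstream sums.
    """
    out = np.zeros((graph.n_positions, N_AA))
    for i, aa_idx in enumerate(graph.aa_index_arrays()):
        sums, counts = _grouped(state.E[i] * state.P[i], aa_idx)
        present = counts > 0
        out[i, present] = sums[present] / counts[present] ** gamma
    return out


def backbone_weights(
    energy_tables: Sequence[np.ndarray], kT: float
) -> np.ndarray:
    """Per-position Boltzmann weights of the M backbones (M x N, columns sum to 1).

    Position i weighs backbone bb by ``exp(-sum_aa E_bb(i,aa) / kT)``,
    normalised over backbones; shift-invariant per position.  ``kT = inf``
    gives exactly uniform 1/M.
    """
    tables = [np.asarray(t, dtype=float) for t in energy_tables]
    if not tables:
        raise ValidationError("need at least one backbone energy table")
    if any(t.shape != tables[0].shape for t in tables):
        raise ValidationError("backbone energy tables differ in shape")
    sums = np.stack([t.sum(axis=1) for t in tables])  # (M, N)
    logits = -(sums - sums.min(axis=0, keepdims=True)) / kT
    w = np.exp(logits)
    return w / w.sum(axis=0, keepdims=True)


def combine_backbones(aggregate: EnsembleAggregate) -> SpecificityProfile:
    """Weighted average of the per-backbone amino-acid tables.

    Entry (i, aa) is ``sum_bb P_aa(bb,i,aa) * W(bb,i)``.  Rows sum to 1
    automatically because each is a convex combination of distributions.
    """
    freq = np.einsum("mna,mn->na", aggregate.aa_probs, aggregate.weights)
    labels = aggregate.position_labels or None
    return SpecificityProfile(freq, labels)


def enrich_over_background(
    profile: SpecificityProfile, background: SpecificityProfile
) -> SpecificityProfile:
    """Divide by a background composition and renormalise each row.

    A single-row background broadcasts to all positions.  Zero background
    frequencies are refused because the quotient is undefined there.
    """
    bg = background.freq
    if bg.shape[0] == 1:
        bg = np.broadcast_to(bg, profile.freq.shape)
    elif bg.shape[0] != profile.n_positions:
        raise ValidationError(
            f"background has {bg.shape[0]} rows; expected 1 or {profile.n_positions}"
        )
    if np.any(bg <= 0):
        raise ValidationError(
            "background profile has zero frequencies; smooth the background "
            "(e.g. add a pseudo-count) before enrichment"
        )
    quotient = profile.freq / bg
    return SpecificityProfile(
        quotient / quotient.sum(axis=1, keepdims=True), list(profile.positions)
    )


@dataclass
class PredictionResult:
    """End-to-end prediction output with per-backbone diagnostics."""

    profile: SpecificityProfile
    aggregate: EnsembleAggregate
    diagnostics: dict


def predict_specificity(
    graphs: Sequence[InteractionGraph],
    params: MFParameters | None = None,
    background: SpecificityProfile | None = None,
) -> PredictionResult:
    """Full pipeline: SCMF per backbone, aggregate, weight, average, enrich.

    All graphs must share position count and labels.  If no backbone
    converged a warning is recorded in the diagnostics (and emitted), but
    the result is still returned — the caller decides what to do with it.
    """
    if params is None:
        params = MFParameters()
    if not graphs:
        raise ValidationError("need at least one interaction graph")
    labels = list(graphs[0].position_labels)
    for g in graphs[1:]:
        if list(g.position_labels) != labels:
            raise ValidationError(
                f"backbone '{g.backbone_id}' positions {g.position_labels} "
                f"do not match '{graphs[0].backbone_id}' positions {labels}"
            )

    states = [run_scmf(g, params) for g in graphs]
    aa_probs = np.stack(
        [aa_probabilities(s, g, params.gamma) for s, g in zip(states, graphs)]
    )
    aa_energies = np.stack(
        [backbone_aa_energies(s, g, params.gamma) for s, g in zip(states, graphs)]
    )
    weights = backbone_weights(aa_energies, params.kT)
    aggregate = EnsembleAggregate(aa_probs, aa_energies, weights, labels)
    profile = combine_backbones(aggregate)
    if background is not None:
        profile = enrich_over_background(profile, background)

    diagnostics = {
        "backbones": [
            {
                "backbone_id": g.backbone_id,
                "iterations": s.iterations,
                "converged": s.converged,
                "residual": s.residual,
            }
            for g, s in zip(graphs, states)
        ],
        "n_backbones": len(graphs),
        "all_converged": all(s.converged for s in states),
    }
    if not any(s.converged for s in states):
        msg = "no backbone reached SCMF convergence; profile may be unreliable"
        diagnostics["warning"] = msg
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
    return PredictionResult(profile, aggregate, diagnostics)
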