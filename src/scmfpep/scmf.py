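"""Single-backbone self-consistent mean-field (SCMF) iteration.

Each peptide position carries a probability distribution over its rotamers.
The mean-field energy of rotamer ``r`` at position ``i`` is its one-body
energy plus the probability-weighted average of its two-body energies with
every rotamer at every other position::

    E(i,r) = e(i_r) + sum_{j != i} sum_s e(i_r, j_s) * P(j,s)

New probabilities follow from a Boltzmann distribution at temperature kT::

    P(j,s) = exp(-E(j,s)/kT) / sum_x exp(-E(j,x)/kT)

and the two equations are iterated to self-consistency.  Convergence is
stabilised by a memory term, ``P_x = lam * P_{x-1} + (1-lam) * P_x``, and
by truncating every input energy (one-body and two-body alike) at an upper
threshold so that a single steric clash cannot dominate the field.  The
update is simultaneous (Jacobi-style): each sweep computes all energies
from the previous full probability matrix.

This module is fully deterministic; the only RNG seed in
:class:`MFParameters` exists for downstream stochastic consumers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .interaction_model import InteractionGraph, ValidationError

__all__ = [
    "MFParameters",
    "ProbabilityMatrix",
    "MFState",
    "init_probabilities",
    "truncate_energy",
    "mean_field_energies",
    "boltzmann_probabilities",
    "damped_update",
    "run_scmf",
    "fixed_point_residual",
]


@dataclass(frozen=True)
class MFParameters:
    """Free parameters and convergence controls of the mean-field model.

    Attributes
    ----------
    kT:
        Boltzmann temperature in energy units (beta = 1/kT).  The most
        system-dependent parameter; 0.6 works well for PDZ-like systems.
    lam:
        Memory weight in [0, 1) for the damped update.
    gamma:
        Rotamer-count exponent in [0, 1] used downstream when aggregating
        rotamer probabilities into amino-acid probabilities.
    threshold:
        Upper truncation cap applied to every input energy.
    tol:
        Convergence tolerance on the max absolute probability change.
    max_iter:
        Iteration cap; hitting it is reported, not raised.
    seed:
        RNG seed for stochastic consumers of these parameters.
    """

    kT: float = 0.6
    lam: float = 0.5
    gamma: float = 0.8
    threshold: float = 100.0
    tol: float = 1e-7
    max_iter: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.kT > 0:
            raise ValidationError("kT must be > 0")
        if not 0 <= self.lam < 1:
            raise ValidationError("lam must be in [0, 1)")
        if not 0 <= self.gamma <= 1:
            raise ValidationError("gamma must be in [0, 1]")
        if not self.threshold > 0:
            raise ValidationError("threshold must be > 0")
        if not self.tol > 0:
            raise ValidationError("tol must be > 0")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")

    def replace(self, **kwargs) -> "MFParameters":
        return replace(self, **kwargs)


class ProbabilityMatrix:
    """Per-position probability vectors over that position's rotamers.

    Conceptually an N x K_max matrix; stored ragged as one 1-D array per
    position because rotamer counts differ between positions.
    """

    def __init__(self, rows: Sequence[np.ndarray], *, validate: bool = True):
        self.rows = [np.asarray(r, dtype=float) for r in rows]
        if validate:
            self.validate()

    def validate(self) -> None:
        for j, row in enumerate(self.rows):
            if np.any(row < 0):
                raise ValidationError(f"position {j}: negative probability")
            if abs(row.sum() - 1.0) > 1e-9:
                raise ValidationError(
                    f"position {j}: probabilities sum to {row.sum()!r}, not 1"
                )

    def __len__(self) -> int:
        return len(self.rows)

    def __getitem__(self, j: int) -> np.ndarray:
        return self.rows[j]

    def copy(self) -> "ProbabilityMatrix":
        return ProbabilityMatrix([r.copy() for r in self.rows], validate=False)

    def max_abs_diff(self, other: "ProbabilityMatrix") -> float:
        return max(
            float(np.max(np.abs(a - b))) for a, b in zip(self.rows, other.rows)
        )


@dataclass
class MFState:
    """Result of an SCMF run: final probabilities, energies, diagnostics."""

    P: ProbabilityMatrix
    E: list[np.ndarray]
    iterations: int
    converged: bool
    residual: float


def init_probabilities(graph: InteractionGraph) -> ProbabilityMatrix:
    """Uniform start: P(j, s) = 1/K_j for every rotamer s at position j."""
    return ProbabilityMatrix(
        [np.full(k, 1.0 / k) for k in graph.rotamer_counts], validate=False
    )


def truncate_energy(e: np.ndarray | float, threshold: float):
    """Clamp energies at the upper threshold; favourable energies untouched."""
    return np.minimum(e, threshold)


def _truncated_tables(graph: InteractionGraph, threshold: float):
    one_body = [truncate_energy(e, threshold) for e in graph.one_body]
    blocks = {
        pair: truncate_energy(b, threshold) for pair, b in graph.two_body.items()
    }
    return one_body, blocks


def _field_energies(
    one_body: list[np.ndarray],
    blocks: dict[tuple[int, int], np.ndarray],
    P: ProbabilityMatrix,
) -> list[np.ndarray]:
    E = [e.copy() for e in one_body]
    for (i, j), block in blocks.items():
        E[i] += block @ P[j]
        E[j] += block.T @ P[i]
    return E


def mean_field_energies(
    graph: InteractionGraph, P: ProbabilityMatrix, params: MFParameters
) -> list[np.ndarray]:
    """Mean-field energy of every rotamer under the current probabilities.

    Truncation applies independently to each one-body energy and each
    two-body entry before the probability-weighted sum, keeping the field
    linear in P.
    """
    if len(P) != graph.n_positions or any(
        len(P[j]) != k for j, k in enumerate(graph.rotamer_counts)
    ):
        raise ValidationError("probability matrix shape does not match graph")
    one_body, blocks = _truncated_tables(graph, params.threshold)
    return _field_energies(one_body, blocks, P)


def boltzmann_probabilities(
    E: Sequence[np.ndarray], kT: float
) -> ProbabilityMatrix:
    """Per-position Boltzmann distribution (softmax of -E/kT).

    The position minimum is subtracted before exponentiating, so the result
    is invariant to adding a constant to all energies at one position and
    never underflows to an all-zero row.
    """
    rows = []
    for e in E:
        w = np.exp(-(e - e.min()) / kT)
        rows.append(w / w.sum())
    return ProbabilityMatrix(rows, validate=False)


def damped_update(
    P_prev: ProbabilityMatrix, P_new: ProbabilityMatrix, lam: float
) -> ProbabilityMatrix:
    """Convex combination lam * P_prev + (1-lam) * P_new (rows stay normalised)."""
    return ProbabilityMatrix(
        [lam * a + (1.0 - lam) * b for a, b in zip(P_prev.rows, P_new.rows)],
        validate=False,
    )


def run_scmf(graph: InteractionGraph, params: MFParameters) -> MFState:
    """Iterate the mean-field equations to self-consistency.

    Starting from the uniform distribution, each sweep recomputes all
    mean-field energies from the current probability matrix and proposes
    the corresponding Boltzmann distribution.  Convergence is declared when
    the proposed (undamped) update would change no entry of P by more than
    ``tol`` — the returned state therefore satisfies
    ``fixed_point_residual(graph, P, params) <= tol`` by construction, and
    its energies are the field of the returned P.  While unconverged, the
    proposal is blended with the previous matrix using the memory weight
    ``lam`` to stabilise the iteration.  Stops after ``max_iter`` sweeps at
    the latest; non-convergence is reported via the ``converged`` flag,
    never raised.  Fully deterministic.
    """
    one_body, blocks = _truncated_tables(graph, params.threshold)
    P = init_probabilities(graph)
    residual = np.inf
    for iterations in range(1, params.max_iter + 1):
        E = _field_energies(one_body, blocks, P)
        proposed = boltzmann_probabilities(E, params.kT)
        residual = proposed.max_abs_diff(P)
        if residual <= params.tol:
            return MFState(P=P, E=E, iterations=iterations, converged=True,
                           residual=residual)
        P = damped_update(P, proposed, params.lam)
    E = _field_energies(one_body, blocks, P)  # keep E consistent with final P
    return MFState(P=P, E=E, iterations=params.max_iter, converged=False,
                   residual=residual)


def fixed_point_residual(
    graph: InteractionGraph, P: ProbabilityMatrix, params: MFParameters
) -> float:
    """Max abs difference between P and one undamped mean-field sweep of P.

    Zero exactly at a self-consistent fixed point of the two equations.
    """
    E = mean_field_energies(graph, P, params)
    return P.max_abs_diff(boltzmann_probabilities(E, params.kT))
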