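"""Synthetic interaction graphs, ensembles, sequences, and an exact oracle.

The generator emulates the structure of Rosetta-style rotamer interaction
graphs — per-rotamer intrinsic energies on the vertices, pairwise
rotamer-rotamer couplings on a sparse set of edges — without any claim to
physically realistic energies.  Amino acids deliberately have unequal
rotamer counts (serine/threonine-like residues many, glycine/alanine one)
so that the rotamer-count correction in the aggregation step is exercised
meaningfully.

:func:`brute_force_marginals` enumerates every rotamer assignment of a
small graph and computes the exact Boltzmann marginals and partition
function; it is the independent ground truth the mean-field approximation
is validated against.  The oracle uses untruncated energies: truncation is
a mean-field device, not part of the physical distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .interaction_model import (
    AA_INDEX,
    AMINO_ACIDS,
    N_AA,
    InteractionGraph,
    SequenceSet,
    SpecificityProfile,
    ValidationError,
)

__all__ = [
    "DEFAULT_ROTAMER_MULTIPLICITY",
    "ToyEnergyModel",
    "BruteForceResult",
    "generate_toy_graph",
    "generate_ensemble",
    "brute_force_marginals",
    "sample_sequences",
]

#: Rotamer counts per amino acid.  The skew (S/T/R/K many rotamers, G/A one
#: each) mimics the shape of backbone-dependent rotamer libraries; the
#: exact counts are arbitrary fixture constants.
DEFAULT_ROTAMER_MULTIPLICITY: dict[str, int] = {
    "A": 1, "C": 2, "D": 3, "E": 4, "F": 2, "G": 1, "H": 3, "I": 3,
    "K": 5, "L": 3, "M": 4, "N": 3, "P": 2, "Q": 4, "R": 6, "S": 6,
    "T": 6, "V": 2, "W": 2, "Y": 2,
}


@dataclass(frozen=True)
class ToyEnergyModel:
    """Parameters of the synthetic interaction-graph generator.

    Attributes
    ----------
    aa_preference:
        Map position index -> {amino acid: energy offset}.  Negative
        offsets favour that amino acid at that position; unlisted pairs
        get offset 0.
    rotamer_strain:
        Std-dev of the Gaussian noise added independently to every
        rotamer's one-body energy.
    coupling_strength:
        Std-dev of the Gaussian entries of each two-body block.
    coupling_density:
        Fraction of position pairs that receive a two-body block.
    rotamer_multiplicity:
        Map amino acid -> rotamer count (unequal by design).
    alphabet:
        Amino acids present at every position; the full 20 by default,
        restrict it to keep brute-force enumeration feasible.
    seed:
        Fixes every random draw.
    """

    aa_preference: Mapping[int, Mapping[str, float]] = field(default_factory=dict)
    rotamer_strain: float = 0.25
    coupling_strength: float = 0.5
    coupling_density: float = 0.3
    rotamer_multiplicity: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_ROTAMER_MULTIPLICITY)
    )
    alphabet: str = AMINO_ACIDS
    seed: int = 0

    def __post_init__(self) -> None:
        if any(k < 1 for k in self.rotamer_multiplicity.values()):
            raise ValidationError("rotamer multiplicities must be >= 1")
        if not 0 <= self.coupling_density <= 1:
            raise ValidationError("coupling_density must be in [0, 1]")
        bad = [aa for aa in self.alphabet if aa not in AA_INDEX]
        if bad:
            raise ValidationError(f"non-canonical alphabet letter(s) {bad}")


def generate_toy_graph(
    n_positions: int,
    model: ToyEnergyModel,
    backbone_id: str = "toy",
) -> InteractionGraph:
    """Draw one seeded interaction graph from the toy energy model.

    One-body energy of each rotamer = the amino-acid preference offset of
    its position plus Normal(0, rotamer_strain) strain.  A seeded random
    subset of position pairs (fraction ``coupling_density``) receives a
    Normal(0, coupling_strength) two-body block.  Deterministic under seed.
    """
    if n_positions < 1:
        raise ValidationError("n_positions must be >= 1")
    rng = np.random.default_rng(model.seed)
    rotamer_aas, one_body = [], []
    for i in range(n_positions):
        prefs = model.aa_preference.get(i, {})
        aas, energies = [], []
        for aa in model.alphabet:
            k = model.rotamer_multiplicity.get(aa, 1)
            offset = prefs.get(aa, 0.0)
            for _ in range(k):
                aas.append(aa)
                energies.append(offset + rng.normal(0.0, model.rotamer_strain))
        rotamer_aas.append(np.array(aas, dtype="<U1"))
        one_body.append(np.array(energies))

    two_body: dict[tuple[int, int], np.ndarray] = {}
    ks = [len(a) for a in rotamer_aas]
    for i in range(n_positions):
        for j in range(i + 1, n_positions):
            if rng.random() < model.coupling_density:
                two_body[(i, j)] = rng.normal(
                    0.0, model.coupling_strength, size=(ks[i], ks[j])
                )

    labels = [f"P{i + 1}" for i in range(n_positions)]
    return InteractionGraph(backbone_id, labels, rotamer_aas, one_body, two_body)


def generate_ensemble(
    base: ToyEnergyModel,
    n_backbones: int,
    perturbation_scale: float,
    n_positions: int,
) -> list[InteractionGraph]:
    """Backbone ensemble: the base graph plus seeded Gaussian energy jitter.

    All backbones share positions and rotamers; backbone ``k`` adds
    Normal(0, perturbation_scale) noise to every one-body and two-body
    energy of the base graph.  ``perturbation_scale = 0`` yields M
    identical graphs.
    """
    if n_backbones < 1:
        raise ValidationError("n_backbones must be >= 1")
    base_graph = generate_toy_graph(n_positions, base)
    rng = np.random.default_rng(np.random.SeedSequence([base.seed, 0xB8]))
    ensemble = []
    for k in range(n_backbones):
        g = base_graph.copy()
        g.backbone_id = f"bb{k}"
        for i in range(g.n_positions):
            g.one_body[i] = g.one_body[i] + rng.normal(
                0.0, perturbation_scale, size=g.one_body[i].shape
            )
        g.two_body = {
            pair: block + rng.normal(0.0, perturbation_scale, size=block.shape)
            for pair, block in g.two_body.items()
        }
        g.validate()
        ensemble.append(g)
    return ensemble


@dataclass
class BruteForceResult:
    """Exact Boltzmann marginals of a small interaction graph."""

    rotamer_marginals: list[np.ndarray]
    aa_marginals: np.ndarray
    log_partition: float

    @property
    def partition(self) -> float:
        return math.exp(self.log_partition)

    def aa_profile(self, positions: list[str] | None = None) -> SpecificityProfile:
        return SpecificityProfile(self.aa_marginals, positions)


def brute_force_marginals(
    graph: InteractionGraph,
    kT: float,
    max_configurations: int = 1_000_000,
) -> BruteForceResult:
    """Exact per-position rotamer and amino-acid Boltzmann marginals.

    Enumerates all ``prod(K_j)`` rotamer assignments, weights each by
    ``exp(-E_total / kT)`` with the untruncated total energy (sum of
    one-body terms plus all pairwise couplings), and marginalises exactly.
    Also returns the log partition function.  Refuses graphs whose
    configuration count exceeds ``max_configurations``.
    """
    ks = graph.rotamer_counts
    total = int(np.prod([float(k) for k in ks]))
    if total > max_configurations:
        raise ValidationError(
            f"{total} configurations exceed the enumeration cap "
            f"{max_configurations}"
        )
    # assignments[p] holds the rotamer index at position p for each of the
    # `total` configurations.
    assignments = np.indices(ks).reshape(len(ks), total)
    energy = np.zeros(total)
    for p, ob in enumerate(graph.one_body):
        energy += ob[assignments[p]]
    for (i, j), block in graph.two_body.items():
        energy += block[assignments[i], assignments[j]]

    e_min = energy.min()
    weights = np.exp(-(energy - e_min) / kT)
    z_shifted = weights.sum()
    log_partition = float(np.log(z_shifted) - e_min / kT)

    rotamer_marginals = [
        np.bincount(assignments[p], weights=weights, minlength=ks[p]) / z_shifted
        for p in range(len(ks))
    ]
    aa_marginals = np.zeros((graph.n_positions, N_AA))
    for p, aa_idx in enumerate(graph.aa_index_arrays()):
        np.add.at(aa_marginals[p], aa_idx, rotamer_marginals[p])
    return BruteForceResult(rotamer_marginals, aa_marginals, log_partition)


def sample_sequences(
    profile: SpecificityProfile,
    n: int,
    seed: int,
    label: str = "recognized",
    id_prefix: str = "seq",
) -> SequenceSet:
    """Draw n peptide sequences position-independently from a profile."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    aa_array = np.array(list(AMINO_ACIDS))
    columns = [
        rng.choice(aa_array, size=n, p=profile.freq[i])
        for i in range(profile.n_positions)
    ]
    sequences = ["".join(col) for col in zip(*columns)]
    return SequenceSet(
        [(f"{id_prefix}{k}", seq) for k, seq in enumerate(sequences)], label
    )
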