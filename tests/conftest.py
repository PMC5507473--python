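"""Shared fixtures: hand-built graphs and profile constructors."""

from __future__ import annotations

import numpy as np
import pytest

from scmfpep import AA_INDEX, N_AA, InteractionGraph, SpecificityProfile


def make_graph(one_body, aas, blocks=None, backbone_id="test"):
    """Build a graph from plain lists.

    ``one_body``: list per position of energy lists; ``aas``: list per
    position of amino-acid strings (one char per rotamer); ``blocks``:
    {(i, j): 2-D list} with i < j, 0-based.
    """
    labels = [f"P{k + 1}" for k in range(len(one_body))]
    return InteractionGraph(
        backbone_id=backbone_id,
        position_labels=labels,
        rotamer_aas=[np.array(list(a)) for a in aas],
        one_body=[np.array(e, dtype=float) for e in one_body],
        two_body={k: np.array(v, dtype=float) for k, v in (blocks or {}).items()},
    )


def point_mass_profile(seq: str) -> SpecificityProfile:
    """Profile putting all mass on one amino acid per position."""
    freq = np.zeros((len(seq), N_AA))
    for i, aa in enumerate(seq):
        freq[i, AA_INDEX[aa]] = 1.0
    return SpecificityProfile(freq)


def random_profile(n_positions: int, seed: int) -> SpecificityProfile:
    rng = np.random.default_rng(seed)
    return SpecificityProfile(rng.dirichlet(np.ones(N_AA), size=n_positions))


@pytest.fixture
def decoupled_graph():
    """Two positions, two rotamers each, no couplings."""
    return make_graph([[0.0, 1.0], [0.5, -0.5]], ["AC", "DG"])


@pytest.fixture
def coupled_graph():
    """Two positions x two rotamers with an anti-aligning coupling block.

    The small one-body asymmetry breaks the degeneracy so the converged
    distribution is a non-trivial fixed point.
    """
    return make_graph(
        [[0.0, 0.3], [0.2, 0.0]],
        ["AC", "DG"],
        blocks={(0, 1): [[0.0, 5.0], [5.0, 0.0]]},
    )
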