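"""Data model and file I/O for rotamer interaction graphs and specificity profiles.

A rotamer interaction graph stores, for one backbone conformation, the
precomputed energetics of every discrete side-chain conformation (rotamer)
a peptide position can adopt: intrinsic "one-body" energies on the vertices
and rotamer-rotamer "two-body" energy blocks on the edges between positions.
A specificity profile is a positions x 20 amino-acid frequency matrix (a
position weight matrix) describing which residues a receptor tolerates at
each peptide position.

File formats
------------
* Interaction graph: one JSON document per backbone ::

      {"backbone_id": str,
       "positions": [{"label": str,
                      "rotamers": [{"aa": "A".."Y", "one_body": float}]}],
       "two_body": [{"i": int, "j": int, "block": [[float]]}]}

  ``i``/``j`` are 1-based position indices with ``i < j``; ``block`` has
  shape ``K_i x K_j``.  A missing block means exactly zero coupling.  All
  in-memory indices are 0-based; the readers/writers below are the only
  place the 1-based mapping occurs.

* Specificity profile: TSV with header ``pos`` followed by the 20 canonical
  amino acids in alphabetical one-letter order, one row per position.

* Sequence sets: plain FASTA.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd
from Bio import SeqIO

#: Canonical amino-acid alphabet, alphabetical one-letter order.  Every
#: positions x 20 matrix in this package uses this column order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: k for k, aa in enumerate(AMINO_ACIDS)}
N_AA = len(AMINO_ACIDS)


class ValidationError(ValueError):
    """An object violates a domain invariant (exit code 1 at the CLI)."""


class SchemaError(ValidationError):
    """A file does not conform to the documented schema."""


class Rotamer(NamedTuple):
    """A single discrete side-chain conformation at a peptide position."""

    position_index: int
    amino_acid: str
    rotamer_index: int


@dataclass
class InteractionGraph:
    """One backbone's precomputed one-body and two-body rotamer energies.

    Parameters
    ----------
    backbone_id:
        Free-form identifier of the backbone conformation.
    position_labels:
        Ordered labels for the N peptide positions (e.g. ``P4 .. P1'``).
    rotamer_aas:
        Per position, an array of one-letter amino-acid codes, one per
        rotamer (length ``K_j``).  Amino acids have unequal rotamer counts.
    one_body:
        Per position, the intrinsic rotamer energies (arbitrary energy
        units, lower = more favourable), aligned with ``rotamer_aas``.
    two_body:
        Sparse map from position pair ``(i, j)`` with ``i < j`` to a
        ``K_i x K_j`` energy block.  An absent pair means zero coupling.
    """

    backbone_id: str
    position_labels: list[str]
    rotamer_aas: list[np.ndarray]
    one_body: list[np.ndarray]
    two_body: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rotamer_aas = [np.asarray(a, dtype="<U1") for a in self.rotamer_aas]
        self.one_body = [np.asarray(e, dtype=float) for e in self.one_body]
        self.two_body = {
            pair: np.asarray(b, dtype=float) for pair, b in self.two_body.items()
        }
        self.validate()

    # ------------------------------------------------------------------
    @property
    def n_positions(self) -> int:
        return len(self.position_labels)

    @property
    def rotamer_counts(self) -> list[int]:
        """K_j for every position j."""
        return [len(a) for a in self.rotamer_aas]

    def aa_index_arrays(self) -> list[np.ndarray]:
        """Per position, the alphabet index of each rotamer's amino acid."""
        return [
            np.array([AA_INDEX[aa] for aa in aas], dtype=np.intp)
            for aas in self.rotamer_aas
        ]

    def pair_block(self, i: int, j: int) -> np.ndarray:
        """Two-body block between positions ``i`` and ``j`` (0-based).

        Absent blocks materialise as zeros; the ``(j, i)`` orientation is
        the transpose of ``(i, j)``, so ``pair_block(i, j)[r, s] ==
        pair_block(j, i)[s, r]`` always holds.
        """
        if i == j:
            raise ValidationError("no two-body block of a position with itself")
        key = (min(i, j), max(i, j))
        block = self.two_body.get(key)
        if block is None:
            ks = self.rotamer_counts
            return np.zeros((ks[i], ks[j]))
        return block if i < j else block.T

    def iter_rotamers(self) -> Iterator[Rotamer]:
        for i, aas in enumerate(self.rotamer_aas):
            for r, aa in enumerate(aas):
                yield Rotamer(i, str(aa), r)

    def copy(self) -> "InteractionGraph":
        return InteractionGraph(
            backbone_id=self.backbone_id,
            position_labels=list(self.position_labels),
            rotamer_aas=[a.copy() for a in self.rotamer_aas],
            one_body=[e.copy() for e in self.one_body],
            two_body={p: b.copy() for p, b in self.two_body.items()},
        )

    # ------------------------------------------------------------------
    def validate(self) -> None:
        n = self.n_positions
        if n < 1:
            raise ValidationError("graph must have at least one position")
        if not (len(self.rotamer_aas) == len(self.one_body) == n):
            raise ValidationError("positions, rotamer_aas and one_body lengths differ")
        for i, (aas, ob) in enumerate(zip(self.rotamer_aas, self.one_body)):
            if len(aas) < 1:
                raise ValidationError(f"position {i} has no rotamers")
            if len(aas) != len(ob):
                raise ValidationError(f"position {i}: rotamer/energy length mismatch")
            bad = [aa for aa in aas if aa not in AA_INDEX]
            if bad:
                raise ValidationError(
                    f"position {i}: non-canonical amino acid(s) {sorted(set(bad))}"
                )
            if not np.all(np.isfinite(ob)):
                raise ValidationError(f"position {i}: non-finite one-body energy")
        ks = self.rotamer_counts
        for (i, j), block in self.two_body.items():
            if not (0 <= i < j < n):
                raise ValidationError(f"two-body pair ({i}, {j}) out of range or not i<j")
            if block.shape != (ks[i], ks[j]):
                raise ValidationError(
                    f"two-body block ({i}, {j}) has shape {block.shape}, "
                    f"expected {(ks[i], ks[j])}"
                )
            if not np.all(np.isfinite(block)):
                raise ValidationError(f"two-body block ({i}, {j}): non-finite energy")


@dataclass
class SpecificityProfile:
    """Positions x 20 amino-acid frequency matrix (rows sum to 1).

    Used for predicted, experimental and background profiles alike.
    """

    freq: np.ndarray
    positions: list[str] | None = None

    def __post_init__(self) -> None:
        self.freq = np.atleast_2d(np.asarray(self.freq, dtype=float))
        if self.positions is None:
            self.positions = [str(k + 1) for k in range(self.freq.shape[0])]
        self.validate()

    @property
    def n_positions(self) -> int:
        return self.freq.shape[0]

    def validate(self) -> None:
        if self.freq.ndim != 2 or self.freq.shape[1] != N_AA:
            raise ValidationError(f"profile must be N x {N_AA}, got {self.freq.shape}")
        if len(self.positions) != self.freq.shape[0]:
            raise ValidationError("position labels do not match frequency rows")
        if np.any(self.freq < 0):
            raise ValidationError("negative frequency entry")
        sums = self.freq.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValidationError(f"profile rows must sum to 1; sums are {sums}")

    @classmethod
    def from_frequencies(
        cls, freq: np.ndarray, positions: list[str] | None = None, *, tol: float = 1e-6
    ) -> "SpecificityProfile":
        """Build a profile, renormalising rows whose sums are within ``tol`` of 1."""
        freq = np.atleast_2d(np.asarray(freq, dtype=float))
        sums = freq.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > tol):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValidationError(
                f"row {bad} sums to {sums[bad]:.6g}, deviating from 1 by more than {tol}"
            )
        return cls(freq / sums[:, None], positions)

    @classmethod
    def uniform(cls, n_positions: int = 1) -> "SpecificityProfile":
        return cls(np.full((n_positions, N_AA), 1.0 / N_AA))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.freq, columns=list(AMINO_ACIDS))
        df.insert(0, "pos", self.positions)
        return df


@dataclass
class SequenceSet:
    """A labelled collection of peptide sequences (recognised or not)."""

    records: list[tuple[str, str]]
    label: str = "recognized"

    @property
    def sequences(self) -> list[str]:
        return [seq for _, seq in self.records]

    def __len__(self) -> int:
        return len(self.records)


# ----------------------------------------------------------------------
# Interaction-graph I/O


def _require(obj: dict, key: str, context: str):
    if key not in obj:
        raise SchemaError(f"{context}: missing field '{key}'")
    return obj[key]


def read_interaction_graph(path: str | Path) -> InteractionGraph:
    """Read and validate one backbone's interaction graph from JSON.

    Raises
    ------
    SchemaError
        If the document is malformed, naming the offending field.
    ValidationError
        If the graph violates an invariant (asymmetric duplicate blocks,
        non-finite energies, out-of-range pairs, ...).
    """
    path = Path(path)
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: not valid JSON ({exc})") from exc

    backbone_id = str(_require(doc, "backbone_id", str(path)))
    positions = _require(doc, "positions", str(path))
    if not isinstance(positions, list) or not positions:
        raise SchemaError(f"{path}: 'positions' must be a non-empty list")

    labels, rotamer_aas, one_body = [], [], []
    for p, pos in enumerate(positions):
        ctx = f"{path}: positions[{p}]"
        labels.append(str(_require(pos, "label", ctx)))
        rotamers = _require(pos, "rotamers", ctx)
        if not isinstance(rotamers, list) or not rotamers:
            raise SchemaError(f"{ctx}: 'rotamers' must be a non-empty list")
        aas, energies = [], []
        for r, rot in enumerate(rotamers):
            rctx = f"{ctx}.rotamers[{r}]"
            aas.append(str(_require(rot, "aa", rctx)))
            e = _require(rot, "one_body", rctx)
            if not isinstance(e, (int, float)) or not math.isfinite(e):
                raise SchemaError(f"{rctx}: 'one_body' must be a finite number")
            energies.append(float(e))
        rotamer_aas.append(np.array(aas, dtype="<U1"))
        one_body.append(np.array(energies))

    two_body: dict[tuple[int, int], np.ndarray] = {}
    for b, entry in enumerate(doc.get("two_body", [])):
        ctx = f"{path}: two_body[{b}]"
        i = _require(entry, "i", ctx)
        j = _require(entry, "j", ctx)
        block = np.asarray(_require(entry, "block", ctx), dtype=float)
        if not isinstance(i, int) or not isinstance(j, int):
            raise SchemaError(f"{ctx}: 'i' and 'j' must be integers")
        if i == j:
            raise ValidationError(f"{ctx}: a position cannot pair with itself")
        # File positions are 1-based; canonicalise to 0-based i < j.
        i0, j0 = i - 1, j - 1
        if i0 > j0:
            i0, j0, block = j0, i0, block.T
        key = (i0, j0)
        if key in two_body:
            if block.shape != two_body[key].shape or not np.array_equal(
                block, two_body[key]
            ):
                raise ValidationError(
                    f"{ctx}: blocks for pair ({i}, {j}) are not symmetric under "
                    "pair swap (block(i,j) must equal transpose of block(j,i))"
                )
            continue
        two_body[key] = block

    return InteractionGraph(backbone_id, labels, rotamer_aas, one_body, two_body)


def write_interaction_graph(graph: InteractionGraph, path: str | Path) -> None:
    """Serialise a graph to JSON; energies round-trip bit-exactly.

    Python's JSON writer emits the shortest decimal string that parses back
    to the same double, so ``read(write(g))`` reproduces ``g`` exactly.  A
    graph with no two-body blocks omits the ``two_body`` section.
    """
    graph.validate()
    doc: dict = {
        "backbone_id": graph.backbone_id,
        "positions": [
            {
                "label": label,
                "rotamers": [
                    {"aa": str(aa), "one_body": float(e)}
                    for aa, e in zip(aas, energies)
                ],
            }
            for label, aas, energies in zip(
                graph.position_labels, graph.rotamer_aas, graph.one_body
            )
        ],
    }
    if graph.two_body:
        doc["two_body"] = [
            {"i": i + 1, "j": j + 1, "block": block.tolist()}
            for (i, j), block in sorted(graph.two_body.items())
        ]
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


# ----------------------------------------------------------------------
# Profile I/O


def read_profile(path: str | Path) -> SpecificityProfile:
    """Read a profile TSV (header ``pos`` + 20 amino acids, canonical order).

    Rows are renormalised if their sums deviate from 1 by at most 1e-6;
    larger deviations, negative entries and unknown columns are errors.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"pos": str})
    expected = ["pos"] + list(AMINO_ACIDS)
    if list(df.columns) != expected:
        unknown = [c for c in df.columns if c not in expected]
        if unknown:
            raise SchemaError(f"{path}: unknown column(s) {unknown}")
        raise SchemaError(
            f"{path}: columns must be exactly {expected}, got {list(df.columns)}"
        )
    freq = df[list(AMINO_ACIDS)].to_numpy(dtype=float)
    if np.any(freq < 0):
        raise ValidationError(f"{path}: negative frequency entry")
    try:
        return SpecificityProfile.from_frequencies(freq, df["pos"].tolist())
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_profile(profile: SpecificityProfile, path: str | Path) -> None:
    """Write a profile TSV with full-precision decimal frequencies."""
    df = profile.to_dataframe()
    with open(path, "w") as fh:
        fh.write("\t".join(df.columns) + "\n")
        for _, row in df.iterrows():
            fh.write(
                str(row["pos"])
                + "\t"
                + "\t".join(repr(float(row[aa])) for aa in AMINO_ACIDS)
                + "\n"
            )


# ----------------------------------------------------------------------
# Sequence-set I/O


def read_sequences(path: str | Path, label: str = "recognized") -> SequenceSet:
    """Read peptide sequences from FASTA.

    Duplicate sequences are preserved (deduplication, where wanted, happens
    during profile construction).  Non-canonical letters are rejected with
    the offending record named.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = sorted({c for c in seq if c not in AA_INDEX})
        if bad:
            raise ValidationError(
                f"{path}: record '{rec.id}' contains non-canonical letter(s) {bad}"
            )
        records.append((rec.id, seq))
    if not records:
        raise ValidationError(f"{path}: no FASTA records found")
    return SequenceSet(records, label)
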