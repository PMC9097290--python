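"""Double-stranded bead topology.

Each nucleotide is represented by three beads at the geometric centers of the
sugar (S), the base (B) and the phosphate group (P).  Base pairs are numbered
i = 1..n along the 5'->3' direction of strand 1; sugars and bases exist for
every i, phosphates for i = 2..n on each strand (the 5'-terminal nucleotide of
each strand has no 5' phosphate), giving N = 6n - 2 beads in total.

Strand 2 runs antiparallel: its 5'->3' direction corresponds to decreasing i,
and its base at index i is the Watson-Crick complement of the strand-1 base.
The phosphate P_{2,i} sits between sugars S_{2,i} and S_{2,i-1}, i.e. the
5' phosphate of nucleotide (2, j) is P_{2, j+1}.

Bonded terms are instantiated per class at every admissible position.  Classes
tagged 5'/3' are step-dependent (their parameters depend on the dinucleotide
step read 5'->3' along the hosting strand); SB and SBB depend on the base
attached to the sugar; BB-WC depends on the Watson-Crick pair.  No term spans
more than one step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .forcefield import ForceFieldParameters, canonical_pair

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: every bonded class with its kind and context type
CLASS_CONTEXT_TYPES: dict[tuple[str, str], str] = {
    ("bond", "5'-SP-3'"): "step",
    ("bond", "5'-PS-3'"): "step",
    ("bond", "5'-BB-3'"): "step",
    ("bond", "SB"): "base",
    ("bond", "BB-WC"): "pair",
    ("angle", "5'-SPS-3'"): "step",
    ("angle", "5'-PSP-3'"): "step",
    ("angle", "5'-PSB-3'"): "step",
    ("angle", "5'-BSP-3'"): "step",
    ("angle", "SBB"): "base",
    ("dihedral", "5'-SPSP-3'"): "step",
    ("dihedral", "5'-PSPS-3'"): "step",
    ("dihedral", "5'-SPSB-3'"): "step",
    ("dihedral", "5'-BSPS-3'"): "step",
    ("dihedral", "5'-PSBB-3'"): "step",
}


class SequenceError(ValueError):
    pass


def validate_sequence(seq: str) -> str:
    seq = seq.strip().upper()
    if not seq:
        raise SequenceError("empty sequence")
    for pos, ch in enumerate(seq, start=1):
        if ch not in _COMPLEMENT:
            raise SequenceError(f"invalid base {ch!r} at position {pos}")
    return seq


def complement_base(base: str) -> str:
    return _COMPLEMENT[base]


def complement_sequence(seq: str) -> str:
    """Reverse complement of ``seq`` (the complementary strand read 5'->3')."""
    seq = validate_sequence(seq)
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class Bead:
    role: str          # 'S', 'P' or 'B'
    strand: int        # 1 or 2
    index: int         # base-pair index, 1-based along strand 1
    base: str          # base letter for B beads, '' otherwise


@dataclass(frozen=True)
class TermInstance:
    kind: str
    class_label: str
    context: str
    atoms: tuple[int, ...]

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.kind, self.class_label, self.context)


@dataclass
class CGStructure:
    """Bead list, bonded-term list and (optionally) coordinates for a duplex."""

    sequence: str
    beads: list[Bead]
    bonded_terms: list[TermInstance]
    coords: Optional[np.ndarray] = None
    _index: dict[tuple[str, int, int], int] = field(default_factory=dict, repr=False)

    @property
    def n(self) -> int:
        return len(self.sequence)

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    def bead_id(self, role: str, strand: int, index: int) -> int:
        return self._index[(role, strand, index)]

    def has_bead(self, role: str, strand: int, index: int) -> bool:
        return (role, strand, index) in self._index

    def sugar_ids(self, strand: int) -> np.ndarray:
        return np.array([self.bead_id("S", strand, i) for i in range(1, self.n + 1)])

    def base_ids(self, strand: int) -> np.ndarray:
        return np.array([self.bead_id("B", strand, i) for i in range(1, self.n + 1)])

    def phosphate_ids(self, strand: int) -> np.ndarray:
        return np.array([self.bead_id("P", strand, i) for i in range(2, self.n + 1)])

    def referenced_parameter_keys(self) -> set[tuple[str, str, str]]:
        return {t.key for t in self.bonded_terms}

    def with_coords(self, coords: np.ndarray) -> "CGStructure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_beads, 3):
            raise ValueError(f"coords shape {coords.shape} != ({self.n_beads}, 3)")
        return CGStructure(self.sequence, self.beads, self.bonded_terms,
                           coords=coords, _index=self._index)


def build_topology(seq: str, params: ForceFieldParameters | None = None) -> CGStructure:
    """Enumerate beads and bonded terms for the blunt-ended duplex with leading
    strand ``seq`` (5'->3').

    If ``params`` is given, every enumerated term is checked against the
    parameter table and a missing entry raises
    :class:`~duplexcg.forcefield.MissingParameterError` naming the term.
    """
    seq = validate_sequence(seq)
    n = len(seq)
    if n < 2:
        raise SequenceError("duplex needs at least 2 base pairs")

    beads: list[Bead] = []
    index: dict[tuple[str, int, int], int] = {}

    def add_bead(role: str, strand: int, i: int, base: str = "") -> None:
        index[(role, strand, i)] = len(beads)
        beads.append(Bead(role, strand, i, base))

    for strand in (1, 2):
        for i in range(1, n + 1):
            base = seq[i - 1] if strand == 1 else _COMPLEMENT[seq[i - 1]]
            if i >= 2:
                add_bead("P", strand, i)
            add_bead("S", strand, i)
            add_bead("B", strand, i, base)

    assert len(beads) == 6 * n - 2

    def bid(role: str, strand: int, i: int) -> int | None:
        return index.get((role, strand, i))

    terms: list[TermInstance] = []

    def add(kind: str, label: str, context: str, atoms: tuple) -> None:
        if any(a is None for a in atoms):
            return
        terms.append(TermInstance(kind, label, context, tuple(int(a) for a in atoms)))

    def add_step_terms(label, S5, S3, B5, B3, Pmid, P5, P3n, Bwc3):
        add("bond", "5'-SP-3'", label, (S5, Pmid))
        add("bond", "5'-PS-3'", label, (Pmid, S3))
        add("bond", "5'-BB-3'", label, (B5, B3))
        add("angle", "5'-SPS-3'", label, (S5, Pmid, S3))
        add("angle", "5'-PSP-3'", label, (P5, S5, Pmid))
        add("angle", "5'-PSB-3'", label, (Pmid, S3, B3))
        add("angle", "5'-BSP-3'", label, (B5, S5, Pmid))
        add("dihedral", "5'-SPSP-3'", label, (S5, Pmid, S3, P3n))
        add("dihedral", "5'-PSPS-3'", label, (P5, S5, Pmid, S3))
        add("dihedral", "5'-SPSB-3'", label, (S5, Pmid, S3, B3))
        add("dihedral", "5'-BSPS-3'", label, (B5, S5, Pmid, S3))
        add("dihedral", "5'-PSBB-3'", label, (Pmid, S3, B3, Bwc3))

    for i in range(1, n):  # step between base pairs i and i+1
        # strand 1: 5'->3' is i -> i+1
        add_step_terms(
            seq[i - 1] + seq[i],
            bid("S", 1, i), bid("S", 1, i + 1), bid("B", 1, i), bid("B", 1, i + 1),
            bid("P", 1, i + 1), bid("P", 1, i), bid("P", 1, i + 2), bid("B", 2, i + 1),
        )
        # strand 2: 5'->3' is i+1 -> i; step label read along strand 2
        add_step_terms(
            _COMPLEMENT[seq[i]] + _COMPLEMENT[seq[i - 1]],
            bid("S", 2, i + 1), bid("S", 2, i), bid("B", 2, i + 1), bid("B", 2, i),
            bid("P", 2, i + 1), bid("P", 2, i + 2), bid("P", 2, i), bid("B", 1, i),
        )

    for i in range(1, n + 1):
        for strand, other in ((1, 2), (2, 1)):
            base = seq[i - 1] if strand == 1 else _COMPLEMENT[seq[i - 1]]
            add("bond", "SB", base, (bid("S", strand, i), bid("B", strand, i)))
            add("angle", "SBB", base,
                (bid("S", strand, i), bid("B", strand, i), bid("B", other, i)))
        add("bond", "BB-WC", canonical_pair(seq[i - 1]),
            (bid("B", 1, i), bid("B", 2, i)))

    structure = CGStructure(seq, beads, terms, _index=index)

    if params is not None:
        for term in terms:
            params.get(*term.key)  # raises MissingParameterError naming the term
    return structure


def bead_type_label(bead: Bead) -> str:
    """Per-bead WCA/charge type: 'S', 'P' or the base letter."""
    return bead.base if bead.role == "B" else bead.role
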