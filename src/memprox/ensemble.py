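"""Core in-memory containers: frame ensembles and atom selections.

A :class:`FrameEnsemble` holds a fixed set of atoms observed over one or
more frames of a slab-geometry simulation box (bilayer normal along z).
Coordinates and box lengths are in Å, charges in elementary charges,
masses in amu.  Per-atom metadata carries a species label (atom/ion name),
a residue label, and a set of role tags drawn from the vocabulary
``{lipid, phosphate_P, amine_N, glycosyl, ion, water}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: Known role tags. Selections may also reference tags actually present.
TAG_VOCABULARY = frozenset(
    {"lipid", "phosphate_P", "amine_N", "glycosyl", "ion", "water"}
)


@dataclass
class FrameEnsemble:
    """Multi-frame coordinate set with per-atom metadata.

    Parameters
    ----------
    coords : ndarray, shape (n_frames, n_atoms, 3)
        Cartesian coordinates in Å.
    box : ndarray, shape (n_frames, 3)
        Orthorhombic box lengths (Dx, Dy, Dz) in Å per frame.
    species : ndarray of str, shape (n_atoms,)
        Species labels, e.g. ``"O2-"``, ``"K+"``, ``"P"``.
    residues : ndarray of str, shape (n_atoms,)
        Residue labels, e.g. ``"POPE"``, ``"POPG"``.
    charges : ndarray of float, shape (n_atoms,)
        Partial charges in e.
    masses : ndarray of float, shape (n_atoms,)
        Atomic masses in amu.
    tags : sequence of frozenset of str, length n_atoms
        Role tags per atom (possibly empty).
    """

    coords: np.ndarray
    box: np.ndarray
    species: np.ndarray
    residues: np.ndarray
    charges: np.ndarray
    masses: np.ndarray
    tags: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        n_frames, n_atoms = self.coords.shape[:2]
        if n_frames < 1:
            raise ValueError("ensemble needs at least one frame")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        self.box = np.asarray(self.box, dtype=float)
        if self.box.shape == (3,):
            self.box = np.tile(self.box, (n_frames, 1))
        if self.box.shape != (n_frames, 3):
            raise ValueError("box must have shape (n_frames, 3)")
        if not np.all(self.box > 0):
            raise ValueError("box lengths must be positive")
        self.species = np.asarray(self.species, dtype=object)
        self.residues = np.asarray(self.residues, dtype=object)
        self.charges = np.asarray(self.charges, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        self.tags = tuple(frozenset(t) for t in self.tags)
        for name, arr in (
            ("species", self.species),
            ("residues", self.residues),
            ("charges", self.charges),
            ("masses", self.masses),
        ):
            if arr.shape != (n_atoms,):
                raise ValueError(f"{name} must have length n_atoms={n_atoms}")
        if len(self.tags) != n_atoms:
            raise ValueError("tags must have one entry per atom")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    def known_species(self) -> set:
        return set(self.species.tolist())

    def known_residues(self) -> set:
        return set(self.residues.tolist())

    def known_tags(self) -> set:
        out: set = set()
        for t in self.tags:
            out |= t
        return out


@dataclass(frozen=True)
class AtomSelection:
    """An ordered, duplicate-free set of atom indices with a label."""

    indices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if idx.ndim != 1:
            raise ValueError("indices must be one-dimensional")
        if idx.size and (np.any(np.diff(idx) <= 0) or idx[0] < 0):
            idx = np.unique(idx)
            if idx[0] < 0:
                raise ValueError("negative atom index")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return int(self.indices.size)


class SelectionError(ValueError):
    pass


# --- tiny selection expression language -------------------------------------
#
# expr     := or_expr
# or_expr  := and_expr ("OR" and_expr)*
# and_expr := unary ("AND" unary)*
# unary    := "NOT" unary | "(" expr ")" | term
# term     := ("tag" | "species" | "residue") ":" value
#
# AND/OR/NOT are case-insensitive keywords; values are matched exactly.


def _tokenize(expr: str) -> list:
    out = []
    for raw in expr.replace("(", " ( ").replace(")", " ) ").split():
        out.append(raw)
    return out


class _Parser:
    def __init__(self, tokens: Sequence[str], ensemble: FrameEnsemble):
        self.tokens = list(tokens)
        self.pos = 0
        self.ens = ensemble

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.or_expr()
        if self.peek() is not None:
            raise SelectionError(f"unexpected token {self.peek()!r}")
        return mask

    def or_expr(self) -> np.ndarray:
        mask = self.and_expr()
        while self.peek() is not None and self.peek().upper() == "OR":
            self.take()
            mask = mask | self.and_expr()
        return mask

    def and_expr(self) -> np.ndarray:
        mask = self.unary()
        while self.peek() is not None and self.peek().upper() == "AND":
            self.take()
            mask = mask & self.unary()
        return mask

    def unary(self) -> np.ndarray:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of expression")
        if tok.upper() == "NOT":
            self.take()
            return ~self.unary()
        if tok == "(":
            self.take()
            mask = self.or_expr()
            if self.take() != ")":
                raise SelectionError("unbalanced parentheses")
            return mask
        return self.term()

    def term(self) -> np.ndarray:
        tok = self.take()
        if ":" not in tok:
            raise SelectionError(f"malformed term {tok!r}; expected kind:value")
        kind, _, value = tok.partition(":")
        kind = kind.lower()
        ens = self.ens
        if kind == "tag":
            known = TAG_VOCABULARY | ens.known_tags()
            if value not in known:
                raise SelectionError(
                    f"unknown tag {value!r}; known tags: {sorted(known)}"
                )
            return np.fromiter(
                (value in t for t in ens.tags), dtype=bool, count=ens.n_atoms
            )
        if kind == "species":
            known = ens.known_species()
            if value not in known:
                raise SelectionError(
                    f"unknown species label {value!r}; known labels: {sorted(known)}"
                )
            return ens.species == value
        if kind == "residue":
            known = ens.known_residues()
            if value not in known:
                raise SelectionError(
                    f"unknown residue label {value!r}; known labels: {sorted(known)}"
                )
            return ens.residues == value
        raise SelectionError(f"unknown selection kind {kind!r}")


def select_atoms(ensemble: FrameEnsemble, expr: str, label: str | None = None) -> AtomSelection:
    """Resolve a selection expression into an ascending atom index set.

    The grammar supports conjunction/disjunction/negation of ``tag:``,
    ``species:`` and ``residue:`` terms, e.g.
    ``"tag:lipid AND NOT tag:glycosyl"`` or ``"species:K+"``.
    Unknown labels raise :class:`SelectionError` listing the known ones.
    """
    tokens = _tokenize(expr)
    if not tokens:
        raise SelectionError("empty selection expression")
    mask = _Parser(tokens, ensemble).parse()
    return AtomSelection(np.flatnonzero(mask), label=label if label is not None else expr)


def selection_from_indices(indices: Iterable[int], label: str = "") -> AtomSelection:
    return AtomSelection(np.asarray(sorted(set(int(i) for i in indices)), dtype=int), label)
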