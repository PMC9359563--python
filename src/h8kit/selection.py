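"""A small deterministic atom-selection language.

Expressions combine primitive predicates with ``and``, ``or``, ``not`` and
parentheses::

    chain A and resnum 134 and name CA
    name CA
    (chain R and resnum 1:18) or (chain R and resnum 40:57)
    resname GLU ASP
    protein
    all

``resnum`` accepts single numbers, ``lo:hi`` / ``lo-hi`` inclusive ranges and
comma-separated lists; an insertion-coded residue is written ``52A``.
Whatever the expression, the result is returned in structure file order
(chain order, then residue order, then atom order), so a union of disjoint
ranges is simply their concatenation in that order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .model import AtomRecord, Residue, Structure

_TOKEN = re.compile(r"\(|\)|[^\s()]+")

_Pred = Callable[[Residue, AtomRecord], bool]


class SelectionError(ValueError):
    pass


def _parse_resnum_item(item: str) -> Callable[[Residue], bool]:
    m = re.fullmatch(r"(-?\d+)([A-Za-z]?)", item)
    if m:
        num, icode = int(m.group(1)), m.group(2).upper()
        return lambda r: r.number == num and r.insertion_code == icode
    m = re.fullmatch(r"(-?\d+)[:\-](-?\d+)", item)
    if m:
        lo, hi = int(m.group(1)), int(m.group(2))
        if lo > hi:
            raise SelectionError(f"empty resnum range {item!r}")
        return lambda r: lo <= r.number <= hi
    raise SelectionError(f"cannot parse resnum item {item!r}")


class _Parser:
    """Recursive-descent parser; 'and' binds tighter than 'or'."""

    _KEYWORDS = {"and", "or", "not", "chain", "resnum", "resname", "name",
                 "protein", "all", "(", ")"}

    def __init__(self, expression: str):
        self.tokens = _TOKEN.findall(expression)
        if not self.tokens:
            raise SelectionError("empty selection expression")
        self.pos = 0
        self.chains_referenced: set[str] = set()

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> _Pred:
        pred = self._or()
        if self.peek() is not None:
            raise SelectionError(f"trailing tokens from {self.peek()!r}")
        return pred

    def _or(self) -> _Pred:
        left = self._and()
        while self.peek() == "or":
            self.take()
            right = self._and()
            left = (lambda a, b: lambda r, at: a(r, at) or b(r, at))(left, right)
        return left

    def _and(self) -> _Pred:
        left = self._unary()
        while self.peek() == "and":
            self.take()
            right = self._unary()
            left = (lambda a, b: lambda r, at: a(r, at) and b(r, at))(left, right)
        return left

    def _unary(self) -> _Pred:
        if self.peek() == "not":
            self.take()
            inner = self._unary()
            return lambda r, at: not inner(r, at)
        if self.peek() == "(":
            self.take()
            inner = self._or()
            if self.take() != ")":
                raise SelectionError("unbalanced parentheses")
            return inner
        return self._primitive()

    def _values(self) -> list[str]:
        vals = []
        while self.peek() is not None and self.peek() not in self._KEYWORDS:
            vals.append(self.take())
        if not vals:
            raise SelectionError("keyword expects at least one value")
        return vals

    def _primitive(self) -> _Pred:
        tok = self.take()
        if tok == "all":
            return lambda r, at: True
        if tok == "protein":
            return lambda r, at: r.is_amino_acid
        if tok == "chain":
            ids = set(self._values())
            self.chains_referenced |= ids
            return lambda r, at: r.chain_id in ids
        if tok == "resname":
            names = {v.upper() for v in self._values()}
            return lambda r, at: r.name3 in names
        if tok == "name":
            names = {v.upper() for v in self._values()}
            return lambda r, at: at.name.upper() in names
        if tok == "resnum":
            items = [_parse_resnum_item(v) for v in self._values()]
            return lambda r, at: any(f(r) for f in items)
        raise SelectionError(f"unknown selection keyword {tok!r}")


@dataclass(frozen=True)
class Selection:
    """A predicate over (chain, residue, atom); resolves deterministically."""

    expression: str

    def _compiled(self) -> tuple[_Pred, set[str]]:
        parser = _Parser(self.expression)
        return parser.parse(), parser.chains_referenced

    def atoms(self, structure: Structure) -> list[tuple[Residue, AtomRecord]]:
        """Matching (residue, atom) pairs in file order.

        An empty result is legitimate, but naming a chain id that does not
        exist in the structure is reported as an error so that typos are
        distinguishable from genuinely empty ranges.
        """
        pred, chains = self._compiled()
        missing = chains - set(structure.chains)
        if missing:
            raise SelectionError(
                f"selection references unknown chain(s) {sorted(missing)}; "
                f"structure has {sorted(structure.chains)}"
            )
        return [
            (r, a)
            for r in structure.residues()
            for a in r.atoms
            if pred(r, a)
        ]

    def atom_indices(self, structure: Structure) -> np.ndarray:
        """Flat indices into ``structure.coords()`` order."""
        pred, chains = self._compiled()
        missing = chains - set(structure.chains)
        if missing:
            raise SelectionError(
                f"selection references unknown chain(s) {sorted(missing)}"
            )
        idx = []
        i = 0
        for r in structure.residues():
            for a in r.atoms:
                if pred(r, a):
                    idx.append(i)
                i += 1
        return np.array(idx, dtype=int)

    def residues(self, structure: Structure) -> list[Residue]:
        """Residues with at least one matching atom, in file order."""
        seen = []
        last = None
        for r, _ in self.atoms(structure):
            if r is not last:
                seen.append(r)
                last = r
        return seen


def select(structure: Structure, expression: str | Selection) -> list[tuple[Residue, AtomRecord]]:
    """Resolve a selection expression on a structure (ordered atom list)."""
    sel = expression if isinstance(expression, Selection) else Selection(expression)
    return sel.atoms(structure)
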