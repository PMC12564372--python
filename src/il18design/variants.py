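"""Amino-acid substitution variants: parsing, enumeration, combination.

Variants are named in mature IL-18 numbering (Tyr1 = 1) with one-letter
codes, e.g. ``E6M`` for Glu6→Met, and multi-site variants joined with
``+``.  The canonical label orders mutations by ascending position, so
``R131G+E6M`` and ``E6M+R131G`` denote the same variant.  Chain
identifiers are deliberately absent from labels; where structures are
involved the chain is carried separately.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: three-letter ↔ one-letter residue code mapping (canonical 20 amino acids;
#: ambiguity codes B/Z/X are intentionally absent and therefore rejected).
THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE = {one: three for three, one in THREE_TO_ONE.items()}

_MUTATION_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


class VariantError(ValueError):
    """Raised for malformed or inconsistent variant specifications."""


@dataclass(frozen=True, order=True)
class Mutation:
    """A single amino-acid substitution, e.g. Glu6→Met (``E6M``)."""

    position: int
    wt_res: str
    mut_res: str

    def __post_init__(self) -> None:
        if self.wt_res not in AA_ALPHABET:
            raise VariantError(f"invalid wild-type residue code {self.wt_res!r}")
        if self.mut_res not in AA_ALPHABET:
            raise VariantError(f"invalid mutant residue code {self.mut_res!r}")
        if self.wt_res == self.mut_res:
            raise VariantError(
                f"silent substitution {self.wt_res}{self.position}{self.mut_res}"
            )
        if self.position < 1:
            raise VariantError(f"position must be >= 1, got {self.position}")

    @property
    def label(self) -> str:
        return f"{self.wt_res}{self.position}{self.mut_res}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclass(frozen=True)
class Variant:
    """A set of mutations with pairwise-distinct positions.

    The empty set is the wild type, labelled ``"WT"``.
    """

    mutations: frozenset[Mutation] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        positions = [m.position for m in self.mutations]
        if len(set(positions)) != len(positions):
            dup = sorted(p for p in set(positions) if positions.count(p) > 1)
            raise VariantError(f"duplicate mutated position(s): {dup}")

    @property
    def label(self) -> str:
        if not self.mutations:
            return "WT"
        return "+".join(m.label for m in sorted(self.mutations))

    @property
    def n_mutations(self) -> int:
        return len(self.mutations)

    @property
    def is_single(self) -> bool:
        return len(self.mutations) == 1

    @property
    def positions(self) -> frozenset[int]:
        return frozenset(m.position for m in self.mutations)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


WILD_TYPE = Variant()


def parse_mutation(token: str) -> Mutation:
    """Parse a single token such as ``"E6M"`` into a :class:`Mutation`."""
    m = _MUTATION_RE.match(token.strip())
    if m is None:
        raise VariantError(f"malformed mutation token {token!r}")
    wt, pos, mut = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    return Mutation(position=pos, wt_res=wt, mut_res=mut)


def parse_variant(label: str) -> Variant:
    """Parse a variant label such as ``"E6M+N111S"`` (or ``"WT"``).

    Token order is irrelevant; the result's :attr:`Variant.label` is
    canonical (ascending position).
    """
    stripped = label.strip()
    if stripped.upper() in ("WT", "WILD-TYPE", "WILDTYPE"):
        return WILD_TYPE
    if not stripped:
        raise VariantError("empty variant label")
    mutations = [parse_mutation(tok) for tok in stripped.split("+")]
    return Variant(frozenset(mutations))


def saturate(sites: Sequence[tuple[str, int]]) -> list[Variant]:
    """In silico saturation mutagenesis: each site to all 19 other residues.

    Parameters
    ----------
    sites
        ``(wt_res, position)`` pairs, e.g. ``[("E", 6), ("N", 111)]``.

    Returns
    -------
    list of single-mutation :class:`Variant`, 19 per site, ordered by
    position then mutant residue.  The wild-type identity substitution is
    never emitted.
    """
    variants: list[Variant] = []
    for wt, pos in sites:
        if wt not in AA_ALPHABET:
            raise VariantError(f"invalid wild-type residue code {wt!r}")
        for aa in AA_ALPHABET:
            if aa == wt:
                continue
            variants.append(Variant(frozenset([Mutation(pos, wt, aa)])))
    variants.sort(key=lambda v: (min(v.positions), v.label))
    return variants


def combine(singles: Iterable[Variant], k: int) -> list[Variant]:
    """All size-``k`` combinations of single mutants with distinct positions.

    Subsets in which two mutations occupy the same position (e.g. R131K
    with R131G) are excluded.  Output order is lexicographic by canonical
    label, hence deterministic.
    """
    if k < 2:
        raise VariantError(f"combination order k must be >= 2, got {k}")
    singles = list(singles)
    for v in singles:
        if not v.is_single:
            raise VariantError(f"combine() takes single-point variants, got {v.label!r}")
    out: list[Variant] = []
    for subset in itertools.combinations(singles, k):
        positions = [next(iter(v.mutations)).position for v in subset]
        if len(set(positions)) != k:
            continue
        out.append(Variant(frozenset(m for v in subset for m in v.mutations)))
    out.sort(key=lambda v: v.label)
    return out


def read_variant_list(path) -> list[Variant]:
    """Read a plain-text variant list, one label per line; '#' comments allowed."""
    variants = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                variants.append(parse_variant(line))
    return variants


def write_variant_list(path, variants: Iterable[Variant]) -> None:
    with open(path, "w") as fh:
        for v in variants:
            fh.write(v.label + "\n")
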