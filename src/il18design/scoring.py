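"""Mutation scoring, ranking and candidate selection.

The mutation score of a variant is the weighted sum of its three
free-energy changes,

    score = w1·ΔΔG_binding + w2·ΔΔG_fold,complex + w3·ΔΔG_fold,ligand,

with weights taken from the activity calibration (all three are
negative, so stabilizing mutations — negative ΔΔG — score positive).
A higher score indicates a more promising design.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

from .calibration import DdgTriple, WeightVector, REFERENCE_WEIGHTS
from .variants import Variant, parse_variant

SCORE_DISPLAY_DECIMALS = 2  # table-style display; full precision kept internally


@dataclass(frozen=True)
class ScoredVariant:
    variant: Variant
    ddg: DdgTriple
    score: float

    @property
    def score_display(self) -> float:
        return round(self.score, SCORE_DISPLAY_DECIMALS)


def mutation_score(ddg: DdgTriple, w: WeightVector) -> float:
    """Weighted sum of the three ΔΔG terms (dimensionless)."""
    wb, wc, wl = w.as_tuple()
    return (
        wb * ddg.ddg_binding
        + wc * ddg.ddg_fold_complex
        + wl * ddg.ddg_fold_ligand
    )


def score_variants(
    ddg: dict[Variant, DdgTriple], w: WeightVector = REFERENCE_WEIGHTS
) -> list[ScoredVariant]:
    return [ScoredVariant(v, t, mutation_score(t, w)) for v, t in ddg.items()]


def rank_variants(scored: Iterable[ScoredVariant]) -> list[ScoredVariant]:
    """Deterministic ranking: score descending, ties broken by ascending
    ΔΔG_binding (binding affinity is the primary design objective), then
    lexicographic label."""
    return sorted(
        scored,
        key=lambda s: (-s.score, s.ddg.ddg_binding, s.variant.label),
    )


def select_candidates(
    scored: Sequence[ScoredVariant], mode: str = "strict_all_negative", n: int | None = None
) -> list[ScoredVariant]:
    """Apply a candidate-selection rule.

    ``strict_all_negative`` keeps variants whose three ΔΔG values are all
    negative (favorable binding and both stabilities); ``top_n`` keeps the
    ``n`` best by rank.
    """
    if mode == "strict_all_negative":
        return [s for s in scored if all(v < 0 for v in s.ddg.as_tuple())]
    if mode == "top_n":
        if n is None or n < 1:
            raise ValueError("top_n selection requires n >= 1")
        return rank_variants(scored)[:n]
    raise ValueError(f"unknown selection mode {mode!r}")


def additive_approximation(
    singles: dict[Variant, DdgTriple], combo: Variant
) -> DdgTriple:
    """Approximate a multi-mutant's ΔΔG triple as the sum of its singles.

    This ignores epistatic coupling between sites and is flagged as an
    approximation wherever it is written out; measured (non-additive)
    triples should be preferred when available.
    """
    by_mutation = {
        next(iter(v.mutations)): t for v, t in singles.items() if v.is_single
    }
    total = [0.0, 0.0, 0.0]
    for m in combo.mutations:
        if m not in by_mutation:
            raise KeyError(f"no single-mutant ΔΔG for {m.label}")
        for i, v in enumerate(by_mutation[m].as_tuple()):
            total[i] += v
    return DdgTriple(*total)


def scored_to_frame(scored: Sequence[ScoredVariant]) -> pd.DataFrame:
    """Tabulate scored variants with the standard column order."""
    return pd.DataFrame(
        {
            "variant": [s.variant.label for s in scored],
            "ddg_binding": [s.ddg.ddg_binding for s in scored],
            "ddg_fold_complex": [s.ddg.ddg_fold_complex for s in scored],
            "ddg_fold_ligand": [s.ddg.ddg_fold_ligand for s in scored],
            "score": [s.score_display for s in scored],
        }
    )


def load_reference_panel() -> pd.DataFrame:
    """The published IL-18 variant ΔΔG panel shipped with the package.

    Columns: ``variant``, the three ΔΔG values (kcal/mol, one decimal as
    published), the published score (``reported_score``) and ``group``
    (control / single / double / multiple).  Scores should always be
    recomputed with :func:`mutation_score`; the reported column exists
    for cross-checking only.
    """
    with resources.files("il18design").joinpath("data/il18_ddg_panel.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["variant"] = [parse_variant(v).label for v in df["variant"]]
    return df
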