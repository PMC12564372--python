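"""Calibration of free-energy changes against in vitro activity.

A panel of characterized IL-18 mutants links three FoldX-style
free-energy changes (kcal/mol) to measured bioactivity:

* ΔΔG_binding — change in binding affinity towards the receptor,
* ΔΔG_fold,complex — change in stability of the ligand/receptor complex,
* ΔΔG_fold,ligand — change in stability of the free ligand.

Each ΔΔG type is regressed (ordinary least squares) on the natural
logarithm of % in vitro activity (wild type = 100%); a negative slope
means destabilizing mutations lose activity.  The Pearson correlation
of each fit, rounded to three decimals, becomes the weight of that ΔΔG
term in the mutation score (see :mod:`il18design.scoring`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .variants import Variant, parse_variant

#: Published calibration constants for the 17-mutant IL-18 validation
#: panel (FoldX ΔΔG vs ln % activity), ordered (binding, folding of
#: complex, folding of free ligand).
REFERENCE_PEARSON_R = (-0.7019, -0.7443, -0.5770)
REFERENCE_REGRESSIONS = (
    (-0.6046, -0.5622),   # ΔΔG_binding:      y = -0.6046 x - 0.5622
    (-0.4544, 0.5580),    # ΔΔG_fold,complex: y = -0.4544 x + 0.5580
    (-0.2829, 0.5701),    # ΔΔG_fold,ligand:  y = -0.2829 x + 0.5701
)


@dataclass(frozen=True)
class DdgTriple:
    """The three relative free-energy changes of one variant (kcal/mol)."""

    ddg_binding: float
    ddg_fold_complex: float
    ddg_fold_ligand: float

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.ddg_binding, self.ddg_fold_complex, self.ddg_fold_ligand)


WT_TRIPLE = DdgTriple(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class ActivityRecord:
    """A variant's in vitro activity as % of wild type (wild type = 100)."""

    variant: Variant
    activity_pct: float

    def __post_init__(self) -> None:
        if not (self.activity_pct > 0):
            raise ValueError(
                f"activity_pct must be > 0 (ln must be defined), got {self.activity_pct}"
            )


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of ΔΔG (y, kcal/mol) on ln % activity (x)."""

    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n: int


@dataclass(frozen=True)
class WeightVector:
    """Scoring weights, one per ΔΔG type (dimensionless).

    Derived by rounding the Pearson correlations of the calibration fits
    to three decimals; ``provenance`` records how they were obtained.
    """

    w_bind: float
    w_fold_complex: float
    w_fold_ligand: float
    provenance: str = "unspecified"

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.w_bind, self.w_fold_complex, self.w_fold_ligand)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "WeightVector":
        with open(path) as fh:
            return cls(**json.load(fh))


#: The published weight vector, reproduced by
#: ``derive_weights`` from ``REFERENCE_PEARSON_R``.
REFERENCE_WEIGHTS = WeightVector(
    -0.702, -0.744, -0.577, provenance="rounded reference Pearson r"
)


def relative_activity(mutant_pct: float, wildtype_pct: float = 100.0) -> float:
    """Activity of a mutant relative to wild type (ratio of percentages)."""
    if not (mutant_pct > 0 and wildtype_pct > 0):
        raise ValueError("activities must be positive")
    return mutant_pct / wildtype_pct


def fit_ddg_activity(
    x: Sequence[float], y: Sequence[float]
) -> RegressionFit:
    """OLS regression of ΔΔG on ln % activity with Pearson correlation.

    Parameters
    ----------
    x
        ln of % in vitro activity per variant (wild type = ln 100).
    y
        one ΔΔG type per variant, kcal/mol.

    The p-value is the two-sided test of zero correlation using the t
    distribution with n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance; regression undefined")
    if np.ptp(y) == 0:
        raise ValueError("y has zero variance; correlation undefined")
    res = stats.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
        n=int(n),
    )


def _round_half_away(v: float, ndigits: int) -> float:
    scale = 10 ** ndigits
    return math.copysign(math.floor(abs(v) * scale + 0.5) / scale, v)


def derive_weights(
    fit_binding: RegressionFit | float,
    fit_fold_complex: RegressionFit | float,
    fit_fold_ligand: RegressionFit | float,
) -> WeightVector:
    """Scoring weights from the three calibration fits.

    Each weight is the Pearson r of the corresponding fit rounded to
    three decimals, half away from zero.  Bare correlation values are
    accepted in place of fits.
    """
    rs = [
        f.pearson_r if isinstance(f, RegressionFit) else float(f)
        for f in (fit_binding, fit_fold_complex, fit_fold_ligand)
    ]
    w = [_round_half_away(r, 3) for r in rs]
    return WeightVector(*w, provenance="pearson_r rounded to 3 decimals")


def predict_activity(ddg: float, fit: RegressionFit) -> float:
    """Estimated ln % activity for a ΔΔG value by inverting the fit line."""
    if fit.slope == 0:
        raise ValueError("cannot invert a zero-slope fit")
    return (ddg - fit.intercept) / fit.slope


def load_activity_panel(path) -> list[ActivityRecord]:
    """Read an activity panel TSV with columns ``variant activity_pct``."""
    df = pd.read_csv(path, sep="\t")
    for col in ("variant", "activity_pct"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    return [
        ActivityRecord(parse_variant(row.variant), float(row.activity_pct))
        for row in df.itertuples(index=False)
    ]


def load_ddg_table(path) -> dict[Variant, DdgTriple]:
    """Read a ΔΔG table TSV with columns
    ``variant ddg_binding ddg_fold_complex ddg_fold_ligand``."""
    df = pd.read_csv(path, sep="\t")
    required = ["variant", "ddg_binding", "ddg_fold_complex", "ddg_fold_ligand"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    return {
        parse_variant(row.variant): DdgTriple(
            float(row.ddg_binding),
            float(row.ddg_fold_complex),
            float(row.ddg_fold_ligand),
        )
        for row in df.itertuples(index=False)
    }


def calibrate(
    activities: Sequence[ActivityRecord],
    ddg: dict[Variant, DdgTriple],
) -> tuple[list[RegressionFit], WeightVector]:
    """Full calibration: three fits (one per ΔΔG type) and the weights.

    Only variants present in both inputs are used; the wild type, if
    present, contributes the point (ln 100, 0, 0, 0).
    """
    shared = [a for a in activities if a.variant in ddg]
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 variants shared between activity panel and ΔΔG table, got {len(shared)}"
        )
    x = [math.log(a.activity_pct) for a in shared]
    fits = []
    for idx in range(3):
        y = [ddg[a.variant].as_tuple()[idx] for a in shared]
        fits.append(fit_ddg_activity(x, y))
    return fits, derive_weights(*fits)
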