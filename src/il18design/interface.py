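"""Per-residue interface energetics: loading and favorable/unfavorable classification.

The input is a per-residue decomposition of a protein-protein binding
energy (kcal/mol) into total, electrostatic, van der Waals and
desolvation terms, as produced by FFT-docking energy decomposition
tools.  Residues with a negative total contribution favor complex
formation; strongly favorable residues (total at or below a key
threshold, default -1 kcal/mol) are interface hotspots; residues with a
positive contribution are unfavorable and are candidates for
substitution.  Receptor-epitope site membership (I/II/III for the
IL-18 receptor interface) is an annotation column supplied with the
data, not derived here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

REQUIRED_COLUMNS = [
    "chain", "res_name", "res_index", "e_total", "e_elec", "e_vdw", "e_desolv", "site",
]

VALID_SITES = {"I", "II", "III", "none"}


@dataclass(frozen=True)
class ResidueEnergy:
    """One interface residue's decomposed binding-energy contribution."""

    chain: str
    res_name: str
    res_index: int
    e_total: float
    e_elec: float
    e_vdw: float
    e_desolv: float
    site: str = "none"

    def __post_init__(self) -> None:
        if self.site not in VALID_SITES:
            raise ValueError(f"site must be one of {sorted(VALID_SITES)}, got {self.site!r}")


@dataclass
class InterfaceClassification:
    """Partition of interface residues by the sign/magnitude of their contribution.

    ``key_residues`` (e_total <= key_threshold) is a subset of
    ``favorable`` (e_total < 0); ``unfavorable`` is e_total > 0.
    Residues with an exactly zero contribution belong to neither class.
    """

    key_threshold: float
    key_residues: list[ResidueEnergy] = field(default_factory=list)
    favorable: list[ResidueEnergy] = field(default_factory=list)
    unfavorable: list[ResidueEnergy] = field(default_factory=list)
    neutral: list[ResidueEnergy] = field(default_factory=list)

    def counts_by_site(self) -> pd.DataFrame:
        """Per-site counts of key / favorable / unfavorable residues."""
        rows = []
        for site in ("I", "II", "III", "none"):
            rows.append({
                "site": site,
                "key": sum(1 for r in self.key_residues if r.site == site),
                "favorable": sum(1 for r in self.favorable if r.site == site),
                "unfavorable": sum(1 for r in self.unfavorable if r.site == site),
            })
        return pd.DataFrame(rows)


def _read_table(path) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ","
    return pd.read_csv(path, sep=sep)


def load_residue_energies(path) -> list[ResidueEnergy]:
    """Load a residue-energy table (TSV or CSV, energies in kcal/mol).

    Required columns: ``chain res_name res_index e_total e_elec e_vdw
    e_desolv site``.  Rows with non-numeric or missing energies are
    rejected with the offending row number (1-based, excluding header).
    """
    df = _read_table(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    records: list[ResidueEnergy] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        vals = {}
        for col in ("e_total", "e_elec", "e_vdw", "e_desolv"):
            raw = getattr(row, col)
            try:
                v = float(raw)
            except (TypeError, ValueError):
                raise ValueError(f"row {i}: non-numeric {col} value {raw!r}")
            if pd.isna(v):
                raise ValueError(f"row {i}: missing {col}")
            vals[col] = v
        records.append(ResidueEnergy(
            chain=str(row.chain), res_name=str(row.res_name),
            res_index=int(row.res_index), site=str(row.site), **vals,
        ))
    return records


def write_residue_energies(path, records: Iterable[ResidueEnergy]) -> None:
    """Write records to TSV with the standard column order."""
    df = pd.DataFrame([r.__dict__ for r in records], columns=REQUIRED_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def classify_interface(
    records: Sequence[ResidueEnergy], key_threshold: float = -1.0
) -> InterfaceClassification:
    """Classify interface residues as key / favorable / unfavorable.

    The key threshold is inclusive: a residue at exactly the threshold
    counts as a key residue.  e_total == 0 is neutral.
    """
    if not records:
        raise ValueError("no residue-energy records to classify")
    cls = InterfaceClassification(key_threshold=key_threshold)
    for r in records:
        if r.e_total < 0:
            cls.favorable.append(r)
            if r.e_total <= key_threshold:
                cls.key_residues.append(r)
        elif r.e_total > 0:
            cls.unfavorable.append(r)
        else:
            cls.neutral.append(r)
    return cls
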