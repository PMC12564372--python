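"""Seeded generators for every input the analysis pipeline consumes.

Real inputs to this kind of study come from external engines (FFT
docking decomposition, FoldX-style ΔΔG scans, MD trajectories).  The
generators here produce statistically analogous data with *planted*
ground truth so that every stage — interface classification, activity
calibration, variant scoring, trajectory metrics — can be tested end to
end without those engines:

* energy tables with known favorable/unfavorable labels,
* a validation panel with a planted linear ΔΔG vs ln(% activity)
  relation plus Gaussian noise,
* an additive-plus-epistatic ΔΔG landscape over mutable positions with
  a recorded best variant,
* idealized structures and harmonic-fluctuation trajectories with an
  elevated-amplitude loop (by default residues 106-112, the β8-β9
  hairpin analogue).

All generators are deterministic per seed (one seeded stream per call).
No attempt is made to mimic force-field values beyond scale (kcal/mol, Å).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .calibration import (
    ActivityRecord, DdgTriple, REFERENCE_REGRESSIONS, REFERENCE_WEIGHTS,
)
from .interface import ResidueEnergy
from .scoring import mutation_score
from .trajectory import Frame, Trajectory
from .variants import ONE_TO_THREE, Mutation, Variant, saturate, combine

AA_CODES = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class GeneratorConfig:
    """Knobs shared by the generators; defaults are the study-scale conditions.

    noise_sd and epistasis_sd are in kcal/mol; amplitudes in Å.
    """

    seed: int = 0
    n_residues: int = 156            # mature IL-18 length
    n_mutants: int = 17              # validation-panel size
    planted_slopes: tuple[float, float, float] = tuple(s for s, _ in REFERENCE_REGRESSIONS)
    planted_intercepts: tuple[float, float, float] = tuple(b for _, b in REFERENCE_REGRESSIONS)
    noise_sd: float = 0.5            # scatter about the ΔΔG-activity line
    epistasis_sd: float = 0.3        # pairwise coupling scale in landscapes
    frac_unfavorable: float = 0.3    # share of positive-energy interface residues
    loop_region: tuple[int, int] = (106, 112)
    loop_amplitude_factor: float = 3.0
    base_amplitude: float = 0.5      # per-coordinate Gaussian displacement, Å
    n_frames: int = 1000
    frame_dt_ns: float = 0.06        # 1000 frames over 60 ns
    rigid_transforms: bool = False   # random global rotation+translation per frame


# ---------------------------------------------------------------------------
# Interface energy tables

def gen_energy_table(cfg: GeneratorConfig) -> tuple[list[ResidueEnergy], list[str]]:
    """Residue-energy records with planted favorable/unfavorable labels.

    Favorable residues draw a strictly negative total (some below the
    -1 kcal/mol hotspot threshold); unfavorable residues a strictly
    positive one.  Electrostatic and van der Waals terms are favorable
    and desolvation compensates, mirroring the decomposition structure
    of docking energetics; the three terms sum to the total.
    """
    if cfg.n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    three_letter = list(ONE_TO_THREE.values())
    records, labels = [], []
    for i in range(1, cfg.n_residues + 1):
        unfavorable = rng.random() < cfg.frac_unfavorable
        if unfavorable:
            e_total = abs(rng.normal(0.8, 0.5)) + 0.05
        else:
            e_total = -(abs(rng.normal(1.2, 1.0)) + 0.05)
        e_elec = -abs(rng.normal(1.0, 0.6))
        e_vdw = -abs(rng.normal(0.8, 0.4))
        e_desolv = e_total - e_elec - e_vdw
        records.append(ResidueEnergy(
            chain="A",
            res_name=str(rng.choice(three_letter)),
            res_index=i,
            e_total=round(e_total, 4),
            e_elec=round(e_elec, 4),
            e_vdw=round(e_vdw, 4),
            e_desolv=round(e_total - round(e_elec, 4) - round(e_vdw, 4), 4),
            site=str(rng.choice(["I", "II", "III"])),
        ))
        labels.append("unfavorable" if unfavorable else "favorable")
    return records, labels


# ---------------------------------------------------------------------------
# Activity validation panels

def gen_validation_set(
    cfg: GeneratorConfig,
) -> tuple[list[ActivityRecord], dict[Variant, DdgTriple]]:
    """A mutant panel with a planted linear ΔΔG vs ln(% activity) relation.

    Activities are log-normal around the tens-of-percent range (the real
    panel spans near-dead to activity-enhanced mutants); each ΔΔG type k
    is ``slope_k * ln(activity) + intercept_k + N(0, noise_sd)``,
    independently per type.  Refuses degenerate panels (all activities
    equal), for which the calibration regression is undefined.
    """
    if cfg.n_mutants < 3:
        raise ValueError("n_mutants must be >= 3")
    rng = np.random.default_rng(cfg.seed)
    positions = rng.choice(
        np.arange(1, cfg.n_residues + 1), size=cfg.n_mutants, replace=False
    )
    activities, ddg = [], {}
    for pos in sorted(int(p) for p in positions):
        wt, mut = rng.choice(list(AA_CODES), size=2, replace=False)
        variant = Variant(frozenset([Mutation(pos, str(wt), str(mut))]))
        activity_pct = float(np.exp(rng.normal(math.log(50.0), 1.2)))
        x = math.log(activity_pct)
        triple = DdgTriple(*(
            s * x + b + rng.normal(0.0, cfg.noise_sd)
            for s, b in zip(cfg.planted_slopes, cfg.planted_intercepts)
        ))
        activities.append(ActivityRecord(variant, activity_pct))
        ddg[variant] = triple
    xs = [a.activity_pct for a in activities]
    if max(xs) == min(xs):
        raise ValueError("degenerate panel: all activities equal")
    return activities, ddg


# ---------------------------------------------------------------------------
# ΔΔG landscapes

@dataclass
class LandscapeTruth:
    """Ground truth recorded alongside a generated ΔΔG landscape."""

    best_variant: Variant                  # additive argmax (epistasis excluded)
    additive_scores: dict[Variant, float] = field(repr=False, default_factory=dict)


def gen_ddg_landscape(
    cfg: GeneratorConfig,
    sites: Sequence[tuple[str, int]],
    n_combo_pool: int = 5,
    max_order: int = 4,
) -> tuple[dict[Variant, DdgTriple], LandscapeTruth]:
    """Saturation singles plus multi-site combinations with epistatic noise.

    Single-mutant triples are drawn i.i.d. per component from
    ``N(0.5, 1.5)`` kcal/mol (most substitutions mildly destabilize; a
    favorable minority emerges, as in saturation scans).  The
    ``n_combo_pool`` best singles by mutation score are combined into
    all position-compatible subsets of order 2..``max_order``; a
    combination's triple is the sum of its singles plus, per component
    and per pair of sites, a coupling term ``N(0, epistasis_sd)``.

    The recorded ground-truth best variant is the score argmax of the
    purely additive landscape; ranking the generated (epistatic) table
    recovers it with high probability when ``epistasis_sd`` is small
    against the score gaps between variants.
    """
    if not sites:
        raise ValueError("sites must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    singles = saturate(sites)
    table: dict[Variant, DdgTriple] = {}
    for v in singles:
        table[v] = DdgTriple(*rng.normal(0.5, 1.5, size=3))

    def score(v: Variant) -> float:
        return mutation_score(table[v], REFERENCE_WEIGHTS)

    pool = sorted(singles, key=score, reverse=True)[:n_combo_pool]
    by_mutation = {next(iter(v.mutations)): v for v in pool}
    additive: dict[Variant, float] = {v: score(v) for v in singles}
    for k in range(2, max_order + 1):
        for combo in combine(pool, k):
            parts = [by_mutation[m] for m in combo.mutations]
            total = np.sum([table[p].as_tuple() for p in parts], axis=0)
            n_pairs = k * (k - 1) // 2
            coupling = rng.normal(0.0, cfg.epistasis_sd, size=(n_pairs, 3)).sum(axis=0)
            additive[combo] = mutation_score(DdgTriple(*total), REFERENCE_WEIGHTS)
            table[combo] = DdgTriple(*(total + coupling))
    best = max(additive, key=lambda v: (additive[v], v.label))
    return table, LandscapeTruth(best_variant=best, additive_scores=additive)


# ---------------------------------------------------------------------------
# Structures and trajectories

@dataclass
class ToyStructure:
    """Idealized extended chain plus (optionally) an engineered H-bond acceptor.

    ``hbond_triple`` gives the (donor, hydrogen, acceptor) atom indices
    of the engineered pair, or ``None`` when no acceptor was placed.
    """

    frame: Frame
    hbond_triple: tuple[int, int, int] | None


def gen_toy_structure(
    n_res: int,
    hbond_distance: float = 2.9,
    hbond_angle_deg: float = 170.0,
    donor_residue: int | None = None,
    with_acceptor: bool = True,
) -> ToyStructure:
    """Extended backbone chain (N, H, CA, C, O per residue) with a
    water-oxygen acceptor engineered at a stated donor-acceptor distance
    and donor-H-acceptor angle from one amide group.

    Geometry is idealized (residues spaced 3.8 Å along x, amide
    hydrogens pointing -y, carbonyl oxygens +y), which makes the
    engineered pair the only geometric hydrogen bond in the structure.
    """
    if n_res < 2:
        raise ValueError("n_res must be >= 2")
    names, res_names, res_ids, chains, elements, coords = [], [], [], [], [], []
    for i in range(n_res):
        t = i * 3.8
        for name, elem, xyz in (
            ("N", "N", (t, 0.0, 0.0)),
            ("H", "H", (t, -1.0, 0.0)),
            ("CA", "C", (t + 1.46, 0.6, 0.0)),
            ("C", "C", (t + 2.5, -0.2, 0.0)),
            ("O", "O", (t + 2.5, 1.03, 0.0)),
        ):
            names.append(name)
            elements.append(elem)
            res_names.append("GLY")
            res_ids.append(i + 1)
            chains.append("A")
            coords.append(xyz)
    triple = None
    if with_acceptor:
        j = donor_residue if donor_residue is not None else (n_res // 2 or 1)
        if not (1 <= j <= n_res):
            raise ValueError("donor_residue out of range")
        base = (j - 1) * 5
        n_pos = np.array(coords[base])       # amide N of residue j
        h_pos = np.array(coords[base + 1])   # its hydrogen
        n_hat = n_pos - h_pos                # unit (|N-H| = 1)
        perp = np.array([1.0, 0.0, 0.0])
        theta = math.radians(hbond_angle_deg)
        c = math.cos(theta)
        # |H-A| from the N-H-A triangle with |N-H|=1, |N-A|=d, angle at H
        disc = c * c - 1.0 + hbond_distance ** 2
        if disc <= 0:
            raise ValueError("no acceptor placement for this distance/angle")
        h_a = c + math.sqrt(disc)
        a_pos = h_pos + h_a * (c * n_hat + math.sin(theta) * perp)
        names.append("O")
        elements.append("O")
        res_names.append("HOH")
        res_ids.append(1)
        chains.append("W")
        coords.append(tuple(a_pos))
        triple = (base, base + 1, len(coords) - 1)
    frame = Frame(
        atom_name=np.array(names, dtype="U6"),
        res_name=np.array(res_names, dtype="U4"),
        res_id=np.array(res_ids, dtype=int),
        chain_id=np.array(chains, dtype="U4"),
        element=np.array(elements, dtype="U2"),
        coords=np.array(coords, dtype=float),
    )
    return ToyStructure(frame=frame, hbond_triple=triple)


def gen_trajectory(reference: Frame, cfg: GeneratorConfig) -> Trajectory:
    """Harmonic-fluctuation trajectory about a reference structure.

    Each frame displaces every atom by an isotropic Gaussian with
    per-residue amplitude ``base_amplitude``, multiplied by
    ``loop_amplitude_factor`` inside ``loop_region`` (flexible-loop
    analogue).  With ``rigid_transforms`` a random global rotation and
    translation is applied per frame to exercise the alignment step.
    """
    if not reference.backbone_mask().any():
        raise ValueError("reference has no backbone atoms")
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.loop_region
    amp = np.full(reference.n_atoms, cfg.base_amplitude)
    in_loop = (reference.res_id >= lo) & (reference.res_id <= hi)
    amp[in_loop] *= cfg.loop_amplitude_factor
    coords = (
        reference.coords[None, :, :]
        + rng.normal(0.0, 1.0, size=(cfg.n_frames, reference.n_atoms, 3))
        * amp[None, :, None]
    )
    if cfg.rigid_transforms:
        for i in range(cfg.n_frames):
            R = Rotation.random(random_state=rng).as_matrix()
            t = rng.uniform(-5.0, 5.0, size=3)
            coords[i] = coords[i] @ R.T + t
    times = np.arange(cfg.n_frames) * cfg.frame_dt_ns
    return Trajectory(
        reference.atom_name, reference.res_name, reference.res_id,
        reference.chain_id, reference.element, coords, times,
    )
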