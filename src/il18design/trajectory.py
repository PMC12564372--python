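"""Trajectory statistics: superposition, RMSD/RMSF, distance pattern,
hydrogen bonds and interaction-distance classes.

Trajectories are exchanged as multi-model PDB (MODEL/ENDMDL records);
coordinates are in Å, residue indices 1-based, insertion codes are not
supported.  All metrics remove global translation/rotation by
least-squares rigid-body superposition (Kabsch) of the backbone (N, CA,
C, O) onto a reference structure, mirroring the alignment of MD
snapshots onto a crystal structure.

Statistical conventions
-----------------------
* RMSD: root-mean-square deviation over a selection after superposition.
* RMSF_i = sqrt(mean_t |r_i(t) - <r_i>|^2), per atom, reported per residue.
* Distance pattern: per residue, the mean over frames of the distance of
  the backbone (N, C, CA, O) geometric center from the origin (0,0,0) of
  the aligned frame — a conformational-drift fingerprint.
* Hydrogen bond: donor-acceptor distance <= 3.5 Å and donor-H-acceptor
  angle >= 150 deg (measured at the hydrogen; 180 deg = linear).
* Contact classes: <= 5 Å "within" favorable range for electrostatic and
  pi interactions (<= 4 Å reported as the strong subset); > 6 Å
  long-range electrostatics.

By MD convention an equilibration span at the start of a trajectory is
excluded from averages; the default analysis window keeps the last 40%
of frames and is configurable everywhere a mean is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

BACKBONE_ATOMS = ("N", "CA", "C", "O")
DEFAULT_DISCARD_FRAC = 0.6  # e.g. keep the last 1000 of 2500 snapshots
RMSD_ACCEPTABLE_MAX = 3.0   # Å; conventional stability marker, not an error

#: Atoms defining the charged-group centroid used for salt-bridge style
#: distances (carboxylate midpoint for Asp/Glu; terminal amine N for Lys;
#: guanidinium C for Arg; imidazole ring centroid for His).
CHARGED_GROUP_ATOMS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "LYS": ("NZ",),
    "ARG": ("CZ",),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}
ANIONIC = {"ASP", "GLU"}
CATIONIC = {"LYS", "ARG", "HIS"}

AROMATIC_RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}


class TrajectoryError(ValueError):
    pass


@dataclass
class Frame:
    """One coordinate set plus shared atom metadata.

    ``coords`` is ``(n_atoms, 3)`` in Å; annotation arrays are parallel
    to the atom axis and identical across frames of one trajectory.
    """

    atom_name: np.ndarray
    res_name: np.ndarray
    res_id: np.ndarray
    chain_id: np.ndarray
    element: np.ndarray
    coords: np.ndarray
    time: float | None = None  # ns

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def backbone_mask(self) -> np.ndarray:
        # water oxygens are named "O" but are not backbone
        return np.isin(self.atom_name, BACKBONE_ATOMS) & (self.res_name != "HOH")

    def ca_mask(self) -> np.ndarray:
        return self.atom_name == "CA"

    def residues(self) -> list[tuple[str, int]]:
        """(chain, res_id) keys in order of first appearance."""
        seen: dict[tuple[str, int], None] = {}
        for c, r in zip(self.chain_id, self.res_id):
            seen.setdefault((str(c), int(r)), None)
        return list(seen)

    def residue_mask(self, chain: str, res_id: int) -> np.ndarray:
        return (self.chain_id == chain) & (self.res_id == res_id)

    def copy(self) -> "Frame":
        return Frame(
            self.atom_name, self.res_name, self.res_id, self.chain_id,
            self.element, self.coords.copy(), self.time,
        )


@dataclass
class Trajectory:
    """A stack of frames sharing one topology; ``coords`` is (n_frames, n_atoms, 3)."""

    atom_name: np.ndarray
    res_name: np.ndarray
    res_id: np.ndarray
    chain_id: np.ndarray
    element: np.ndarray
    coords: np.ndarray
    times: np.ndarray | None = None  # ns per frame

    def __post_init__(self) -> None:
        if self.coords.ndim != 3 or self.coords.shape[0] < 1:
            raise TrajectoryError("coords must be (n_frames >= 1, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atom_name):
            raise TrajectoryError("inconsistent atom count between coords and topology")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> Frame:
        t = None if self.times is None else float(self.times[i])
        return Frame(
            self.atom_name, self.res_name, self.res_id, self.chain_id,
            self.element, self.coords[i], t,
        )

    def frames(self) -> Iterable[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    def residues(self) -> list[tuple[str, int]]:
        return self.frame(0).residues()


def analysis_window(n_frames: int, discard_frac: float = DEFAULT_DISCARD_FRAC) -> slice:
    """Frame slice for averages: drop the leading equilibration fraction."""
    if not (0 <= discard_frac < 1):
        raise TrajectoryError("discard_frac must be in [0, 1)")
    start = int(np.floor(n_frames * discard_frac))
    if start >= n_frames:
        start = n_frames - 1
    return slice(start, n_frames)


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)

def _from_atom_array(arr) -> tuple[np.ndarray, ...]:
    if np.any(arr.ins_code != ""):
        raise TrajectoryError("insertion codes are not supported")
    return (
        arr.atom_name.astype("U6"),
        arr.res_name.astype("U4"),
        arr.res_id.astype(int),
        arr.chain_id.astype("U4"),
        arr.element.astype("U2"),
    )


def read_trajectory(path) -> Trajectory:
    """Read a (multi-model) PDB file into a :class:`Trajectory`."""
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    if isinstance(stack, bst.AtomArray):  # single model
        stack = bst.stack([stack])
    names, res_names, res_ids, chains, elements = _from_atom_array(stack[0])
    return Trajectory(
        names, res_names, res_ids, chains, elements,
        np.asarray(stack.coord, dtype=float),
    )


def read_frame(path, model: int = 1) -> Frame:
    pdb = PDBFile.read(str(path))
    arr = pdb.get_structure(model=model)
    names, res_names, res_ids, chains, elements = _from_atom_array(arr)
    return Frame(names, res_names, res_ids, chains, elements,
                 np.asarray(arr.coord, dtype=float))


def _to_atom_array(frame: Frame) -> bst.AtomArray:
    arr = bst.AtomArray(frame.n_atoms)
    arr.coord = np.asarray(frame.coords, dtype=np.float32)
    arr.atom_name = frame.atom_name
    arr.res_name = frame.res_name
    arr.res_id = frame.res_id
    arr.chain_id = frame.chain_id
    arr.element = frame.element
    arr.hetero = np.array([rn == "HOH" for rn in frame.res_name])
    return arr


def write_trajectory(path, traj: Trajectory) -> None:
    """Write as multi-model PDB (coordinates to PDB precision, 3 decimals)."""
    arrays = [_to_atom_array(traj.frame(i)) for i in range(traj.n_frames)]
    pdb = PDBFile()
    pdb.set_structure(bst.stack(arrays))
    pdb.write(str(path))


def write_frame(path, frame: Frame) -> None:
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(frame))
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Superposition and deviation metrics

def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rigid-body fit of ``mobile`` onto ``reference`` point sets.

    Returns ``(R, t)`` with ``x @ R.T + t`` the fitted coordinates; the
    rotation is proper (det = +1, reflections excluded).
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.shape[0] < 3:
        raise TrajectoryError("superposition needs >= 3 paired atoms")
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    P, Q = mobile - mc, reference - rc
    if np.linalg.matrix_rank(P, tol=1e-8) < 2:
        raise TrajectoryError("degenerate (collinear) atom set")
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - mc @ R.T
    return R, t


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def superpose(
    mobile: Frame, reference: Frame, selection: np.ndarray | None = None
) -> tuple[Frame, float]:
    """Superpose ``mobile`` onto ``reference`` and return (fitted frame, RMSD).

    The fit and the RMSD use ``selection`` (default: backbone N/CA/C/O);
    the returned frame has *all* atoms transformed.
    """
    if selection is None:
        selection = mobile.backbone_mask()
    if mobile.n_atoms != reference.n_atoms:
        raise TrajectoryError("mobile and reference must share a topology")
    R, t = kabsch(mobile.coords[selection], reference.coords[selection])
    fitted = mobile.copy()
    fitted.coords = mobile.coords @ R.T + t
    return fitted, _rmsd(fitted.coords[selection], reference.coords[selection])


def align_trajectory(
    traj: Trajectory, reference: Frame, selection: np.ndarray | None = None
) -> Trajectory:
    """Superpose every frame onto the reference backbone."""
    if selection is None:
        selection = reference.backbone_mask()
    coords = np.empty_like(traj.coords)
    for i in range(traj.n_frames):
        fitted, _ = superpose(traj.frame(i), reference, selection)
        coords[i] = fitted.coords
    return Trajectory(traj.atom_name, traj.res_name, traj.res_id,
                      traj.chain_id, traj.element, coords, traj.times)


def rmsd_series(
    traj: Trajectory, reference: Frame, selection: np.ndarray | None = None
) -> np.ndarray:
    """Per-frame RMSD (Å) to the reference after per-frame superposition."""
    if selection is None:
        selection = reference.backbone_mask()
    out = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        _, out[i] = superpose(traj.frame(i), reference, selection)
    return out


@dataclass
class RmsdSummary:
    mean: float
    sd: float
    window: slice
    acceptable: bool = field(init=False)  # conventional < 3 Å stability marker

    def __post_init__(self) -> None:
        self.acceptable = self.mean < RMSD_ACCEPTABLE_MAX


def rmsd_summary(
    series: np.ndarray, discard_frac: float = DEFAULT_DISCARD_FRAC
) -> RmsdSummary:
    win = analysis_window(len(series), discard_frac)
    vals = series[win]
    return RmsdSummary(mean=float(vals.mean()), sd=float(vals.std()), window=win)


def per_residue_rmsd(
    traj: Trajectory, reference: Frame
) -> tuple[list[tuple[str, int]], np.ndarray]:
    """Residue-wise backbone RMSD per frame after global backbone alignment.

    Returns the residue keys and an (n_residues, n_frames) matrix in Å.
    Residues lacking backbone atoms are excluded (and reported by key
    omission).
    """
    aligned = align_trajectory(traj, reference)
    bb = reference.backbone_mask()
    keys, rows = [], []
    for chain, rid in reference.residues():
        mask = reference.residue_mask(chain, rid) & bb
        if not mask.any():
            continue
        keys.append((chain, rid))
        diff = aligned.coords[:, mask, :] - reference.coords[mask]
        rows.append(np.sqrt(np.mean(np.sum(diff ** 2, axis=2), axis=1)))
    return keys, np.array(rows)


def rmsf(
    traj: Trajectory,
    reference: Frame | None = None,
    selection: str = "CA",
    discard_frac: float = 0.0,
    align: bool = True,
) -> tuple[list[tuple[str, int]], np.ndarray]:
    """Per-residue RMSF (Å) about the mean position over the window.

    The statistic assumes frames share the reference coordinate system;
    with ``align`` (default) every frame is first superposed onto
    ``reference`` (default: first frame) on the backbone — pass
    ``align=False`` for trajectories that are already aligned.
    Fluctuations are measured on the selected atoms (default CA;
    ``"backbone"`` averages the four backbone atoms).
    """
    if reference is None:
        reference = traj.frame(0)
    aligned = align_trajectory(traj, reference) if align else traj
    win = analysis_window(traj.n_frames, discard_frac)
    coords = aligned.coords[win]
    if coords.shape[0] < 1:
        raise TrajectoryError("empty analysis window")
    if selection == "CA":
        sel = reference.ca_mask()
    elif selection == "backbone":
        sel = reference.backbone_mask()
    else:
        raise TrajectoryError(f"unknown selection {selection!r}")
    mean_pos = coords.mean(axis=0)
    flucts = np.sqrt(np.mean(np.sum((coords - mean_pos) ** 2, axis=2), axis=0))
    keys, vals = [], []
    for chain, rid in reference.residues():
        mask = reference.residue_mask(chain, rid) & sel
        if not mask.any():
            continue
        keys.append((chain, rid))
        vals.append(float(np.sqrt(np.mean(flucts[mask] ** 2))))
    return keys, np.array(vals)


def distance_pattern(
    traj: Trajectory,
    reference: Frame,
    discard_frac: float = 0.0,
) -> tuple[list[tuple[str, int]], np.ndarray]:
    """Mean distance of each residue's backbone geometric center to the origin.

    Frames are aligned onto the reference backbone first, so the origin
    is that of the reference coordinate system.  The backbone center
    uses the N, C, CA and O atoms; residues missing any of the four are
    excluded.
    """
    aligned = align_trajectory(traj, reference)
    win = analysis_window(traj.n_frames, discard_frac)
    coords = aligned.coords[win]
    keys, vals = [], []
    for chain, rid in reference.residues():
        mask = reference.residue_mask(chain, rid) & reference.backbone_mask()
        if mask.sum() < len(BACKBONE_ATOMS):
            continue
        centers = coords[:, mask, :].mean(axis=1)      # (n_frames, 3)
        keys.append((chain, rid))
        vals.append(float(np.mean(np.linalg.norm(centers, axis=1))))
    return keys, np.array(vals)


# ---------------------------------------------------------------------------
# Hydrogen bonds

@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond definition (distance at D···A, angle at H)."""

    d_max_donor_acceptor: float = 3.5   # Å
    angle_min_dha: float = 150.0        # degrees; 180 = linear

    def __post_init__(self) -> None:
        if self.d_max_donor_acceptor <= 0:
            raise ValueError("d_max_donor_acceptor must be positive")
        if not (0 < self.angle_min_dha <= 180):
            raise ValueError("angle_min_dha must be in (0, 180]")


COVALENT_DH_MAX = 1.2  # Å; D-H bond inferred by distance when no topology given


def donor_hydrogen_pairs(frame: Frame) -> list[tuple[int, int]]:
    """Covalent (donor, hydrogen) pairs: N/O with an H within 1.2 Å."""
    h_idx = np.flatnonzero(frame.element == "H")
    if h_idx.size == 0:
        raise TrajectoryError(
            "no hydrogens in frame; protonate the structure before H-bond analysis"
        )
    dn_idx = np.flatnonzero(np.isin(frame.element, ("N", "O")))
    pairs = []
    for h in h_idx:
        d2 = np.sum((frame.coords[dn_idx] - frame.coords[h]) ** 2, axis=1)
        j = int(np.argmin(d2))
        if d2[j] <= COVALENT_DH_MAX ** 2:
            pairs.append((int(dn_idx[j]), int(h)))
    return pairs


def dha_angle(d: np.ndarray, h: np.ndarray, a: np.ndarray) -> float:
    """Donor-hydrogen-acceptor angle in degrees, measured at the hydrogen."""
    v1, v2 = d - h, a - h
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_hbonds(
    frame: Frame,
    criteria: HBondCriteria = HBondCriteria(),
    donors: Sequence[tuple[int, int]] | None = None,
    acceptors: Sequence[int] | None = None,
    chains: Sequence[str] | None = None,
) -> list[tuple[int, int, int]]:
    """All (donor, hydrogen, acceptor) atom-index triples meeting the criteria.

    Donors default to N/O atoms with a covalently bound hydrogen
    (distance-inferred); acceptors default to all N/O atoms.  Restricting
    ``chains`` limits both sides to those chains (intra-molecular bonds
    when a single chain is given).  Output is canonically sorted.
    """
    if donors is None:
        donors = donor_hydrogen_pairs(frame)
    if acceptors is None:
        acceptors = np.flatnonzero(np.isin(frame.element, ("N", "O")))
    acceptors = np.asarray(acceptors, dtype=int)
    if chains is not None:
        chains = set(chains)
        donors = [(d, h) for d, h in donors if frame.chain_id[d] in chains]
        acceptors = acceptors[np.isin(frame.chain_id[acceptors], list(chains))]
    found = []
    for d, h in donors:
        da = np.linalg.norm(frame.coords[acceptors] - frame.coords[d], axis=1)
        for a, dist in zip(acceptors, da):
            if a == d or a == h or dist > criteria.d_max_donor_acceptor:
                continue
            ang = dha_angle(frame.coords[d], frame.coords[h], frame.coords[a])
            if ang >= criteria.angle_min_dha:
                found.append((int(d), int(h), int(a)))
    return sorted(found)


def hbond_count_series(
    traj: Trajectory,
    criteria: HBondCriteria = HBondCriteria(),
    chains: Sequence[str] | None = None,
) -> np.ndarray:
    frame0 = traj.frame(0)
    donors = donor_hydrogen_pairs(frame0)  # topology shared across frames
    return np.array([
        len(detect_hbonds(traj.frame(i), criteria, donors=donors, chains=chains))
        for i in range(traj.n_frames)
    ])


def mean_hbond_count(
    traj: Trajectory,
    criteria: HBondCriteria = HBondCriteria(),
    discard_frac: float = DEFAULT_DISCARD_FRAC,
    chains: Sequence[str] | None = None,
) -> float:
    """Mean H-bond count over the analysis window (report rounded to integer)."""
    counts = hbond_count_series(traj, criteria, chains=chains)
    win = analysis_window(traj.n_frames, discard_frac)
    if counts[win].size == 0:
        raise TrajectoryError("empty analysis window")
    return float(counts[win].mean())


# ---------------------------------------------------------------------------
# Interaction-distance classes

@dataclass(frozen=True)
class ContactCriteria:
    """Distance classes for electrostatic / pi interactions.

    ``electro_pi_max`` is the favorable-range ceiling (the conventional
    4-5 Å band; distances <= ``strong_max`` form the strong subset);
    beyond ``longrange_min`` a contact is long-range electrostatic, with
    ``longrange_max`` a reporting cap only.
    """

    electro_pi_max: float = 5.0
    strong_max: float = 4.0
    longrange_min: float = 6.0
    longrange_max: float = 10.0

    def __post_init__(self) -> None:
        if not self.electro_pi_max < self.longrange_min:
            raise ValueError("electro_pi_max must be below longrange_min")

    def classify(self, d: float) -> str:
        if d <= self.electro_pi_max:
            return "strong" if d <= self.strong_max else "within"
        if d > self.longrange_min:
            return "long_range"
        return "neither"


def group_centroid(frame: Frame, chain: str, res_id: int, kind: str) -> np.ndarray:
    """Centroid of a residue's interacting group.

    ``kind`` is ``"charged"`` (salt-bridge style group centroid) or
    ``"ring"`` (aromatic ring centroid).
    """
    mask = frame.residue_mask(chain, res_id)
    if not mask.any():
        raise TrajectoryError(f"residue {chain}:{res_id} not found")
    res_name = str(frame.res_name[mask][0])
    table = CHARGED_GROUP_ATOMS if kind == "charged" else AROMATIC_RING_ATOMS
    if res_name not in table:
        raise TrajectoryError(
            f"residue {res_name} {chain}:{res_id} has no {kind} group"
        )
    atom_names = table[res_name]
    sel = mask & np.isin(frame.atom_name, atom_names)
    if sel.sum() != len(atom_names):
        raise TrajectoryError(
            f"residue {res_name} {chain}:{res_id} is missing {kind}-group atoms"
        )
    return frame.coords[sel].mean(axis=0)


def _partner_kinds(frame: Frame, a, b, contact_type: str):
    res_a = str(frame.res_name[frame.residue_mask(*a)][0]) if frame.residue_mask(*a).any() else None
    res_b = str(frame.res_name[frame.residue_mask(*b)][0]) if frame.residue_mask(*b).any() else None
    if res_a is None or res_b is None:
        missing = a if res_a is None else b
        raise TrajectoryError(f"residue {missing[0]}:{missing[1]} not found")
    if contact_type == "electrostatic":
        return "charged", "charged"
    if contact_type == "anion_pi":
        if res_a in ANIONIC and res_b in AROMATIC_RING_ATOMS:
            return "charged", "ring"
        if res_b in ANIONIC and res_a in AROMATIC_RING_ATOMS:
            return "ring", "charged"
        raise TrajectoryError("anion_pi needs one Asp/Glu and one aromatic partner")
    if contact_type == "cation_pi":
        if res_a in CATIONIC and res_b in AROMATIC_RING_ATOMS:
            return "charged", "ring"
        if res_b in CATIONIC and res_a in AROMATIC_RING_ATOMS:
            return "ring", "charged"
        raise TrajectoryError("cation_pi needs one Lys/Arg/His and one aromatic partner")
    raise TrajectoryError(f"unknown contact type {contact_type!r}")


def contact_timeseries(
    traj: Trajectory,
    pair: tuple[tuple[str, int], tuple[str, int], str],
    criteria: ContactCriteria = ContactCriteria(),
) -> tuple[np.ndarray, list[str]]:
    """Per-frame group-centroid distance (Å) and contact class for one pair.

    ``pair`` is ``((chain_a, res_a), (chain_b, res_b), contact_type)``
    with ``contact_type`` one of ``electrostatic``, ``anion_pi``,
    ``cation_pi``.
    """
    a, b, contact_type = pair
    frame0 = traj.frame(0)
    kind_a, kind_b = _partner_kinds(frame0, a, b, contact_type)
    dists = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        f = traj.frame(i)
        ca = group_centroid(f, a[0], a[1], kind_a)
        cb = group_centroid(f, b[0], b[1], kind_b)
        dists[i] = np.linalg.norm(ca - cb)
    labels = [criteria.classify(d) for d in dists]
    return dists, labels
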