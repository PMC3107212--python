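"""Synthetic PDB-format fixtures with known ground truth.

Three generators cover the whole screen:

* sphere models (pseudo-atoms with a uniform radius) whose volumes and
  pairwise overlaps have closed forms, used as oracles for the volume
  methods;
* idealized extended chains with exact 3.8 A C-alpha spacing, used for
  interface and alignment fixtures;
* full collision scenarios: two two-chain structures sharing a primary
  chain, with the secondary chains built as compact "domains" of atoms
  filling a ball, so that a guaranteed lower bound on their overlap volume
  exists by construction.

The secondary domains are deliberately not realistic folds: filling a ball
of radius ``R_BLOB`` with atoms on a grid guarantees that a slightly smaller
ball is completely covered, so the overlap of two such domains displaced by
``d`` is bounded below by the lens volume of two covered balls. Collision
scenarios keep the displacement in regimes where the gate outcome is
certain (lens bound well above the 2000 A^3 threshold, or total separation
so large that the overlap is exactly zero).

Ground-truth interface sets are recomputed by brute-force double loops over
the constructed coordinates, independent of the KD-tree implementation used
by the screen; the ground-truth RMSD uses a plain SVD (Kabsch) fit,
independent of the quaternion solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from clashscan.structio import (
    Atom, Chain, Residue, StructureCollection, StructureModel, THREE_TO_ONE,
)

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items() if k not in
                ("MSE", "SEC", "PYL", "CSO", "SEP", "TPO", "PTR", "MLY", "HYP")}

CA_SPACING = 3.8  # A, consecutive C-alpha distance in the idealized chain
ZIG = 0.4  # A, alternating transverse C-alpha offset (beta-like zig-zag; a
#            perfectly collinear trace would make superposition degenerate)
_CA_STEP_X = math.sqrt(CA_SPACING ** 2 - (2 * ZIG) ** 2)
CONTACT_HEIGHT = 4.6  # A, height of a secondary contact atom above its P residue
R_BLOB = 10.0  # A, radius of the ball the secondary domain fills
BLOB_GRID = 1.7  # A, atom grid spacing inside the domain ball
BLOB_CENTER_Z = 16.0  # A, height of the domain center above the chain plane

# backbone offsets relative to the C-alpha, all in the chain plane (z = 0)
_BACKBONE = {
    "N": np.array([-1.0, 0.8, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.0, 0.8, 0.0]),
    "O": np.array([1.2, 2.0, 0.0]),
    "CB": np.array([0.0, -1.5, 0.0]),
}
_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


def make_sphere_model(centers: Sequence[Sequence[float]], radius: float,
                      entry_id: str = "sphr") -> StructureModel:
    """One pseudo-atom per center, all with the given vdW radius."""
    if len(centers) == 0:
        raise ValueError("need at least one center")
    residues = [
        Residue(("A", i + 1, ""), "GLY", "G",
                [Atom("CA", "C", np.asarray(c, dtype=float), vdw_radius=radius)])
        for i, c in enumerate(centers)
    ]
    return StructureModel(entry_id, 1, [Chain("A", residues)])


def sphere_volume(radius: float) -> float:
    return 4.0 / 3.0 * math.pi * radius ** 3


def lens_volume(r1: float, r2: float, d: float) -> float:
    """Intersection volume of two spheres of radii r1, r2 with centers d apart."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return sphere_volume(min(r1, r2))
    return (math.pi * (r1 + r2 - d) ** 2
            * (d * d + 2 * d * (r1 + r2) - 3 * (r1 - r2) ** 2)
            / (12 * d))


def make_ideal_chain(sequence: str, chain_id: str = "A",
                     origin: Sequence[float] = (0.0, 0.0, 0.0),
                     axis: Sequence[float] = (1.0, 0.0, 0.0)) -> Chain:
    """Deterministic extended chain: N, CA, C, O (+ CB except glycine).

    C-alpha atoms advance along the axis with an alternating transverse
    offset (a planar, beta-strand-like zig-zag) so that consecutive
    C-alpha atoms are exactly 3.8 A apart; all backbone atoms lie in the
    plane spanned by the axis and the transverse direction.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    # orthonormal frame (axis, u, w): backbone lies in the axis-u plane,
    # w is the out-of-plane direction that secondary contacts approach from
    ref = np.array([0.0, 1.0, 0.0]) if abs(axis[1]) < 0.9 else np.array([0.0, 0.0, 1.0])
    w = np.cross(axis, ref)
    w /= np.linalg.norm(w)
    u = np.cross(w, axis)
    frame = np.column_stack([axis, u, w])
    origin = np.asarray(origin, dtype=float)

    residues = []
    for i, letter in enumerate(sequence):
        name3 = ONE_TO_THREE.get(letter.upper())
        if name3 is None:
            raise ValueError(f"nonstandard residue letter {letter!r}")
        ca = origin + i * _CA_STEP_X * axis + ((-1) ** i) * ZIG * u
        atoms = []
        for atom_name, offset in _BACKBONE.items():
            if atom_name == "CB" and name3 == "GLY":
                continue
            atoms.append(Atom(atom_name, _ELEMENTS[atom_name], ca + frame @ offset))
        residues.append(Residue((chain_id, i + 1, ""), name3, letter.upper(), atoms))
    return Chain(chain_id, residues)


def _ball_grid(center: np.ndarray, radius: float, spacing: float) -> np.ndarray:
    n = int(math.floor(radius / spacing))
    ax = np.arange(-n, n + 1) * spacing
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    pts = pts[np.linalg.norm(pts, axis=1) <= radius]
    return pts + center

def covered_ball_radius(radius: float = R_BLOB, spacing: float = BLOB_GRID,
                        atom_radius: float = 1.52) -> float:
    """Radius of the ball guaranteed to be fully covered by the domain atoms.

    Any point within ``radius`` of the center is within half a grid diagonal
    of a grid point inside the ball; adding the smallest vdW radius present
    gives the covered radius.
    """
    return radius - spacing * math.sqrt(3) / 2 + atom_radius


def make_domain_chain(center: Sequence[float], chain_id: str,
                      radius: float = R_BLOB, spacing: float = BLOB_GRID,
                      start_resnum: int = 1) -> Chain:
    """Compact pseudo-domain: glycine residues whose atoms fill a ball."""
    pts = _ball_grid(np.asarray(center, dtype=float), radius, spacing)
    names = ["N", "CA", "C", "O"]
    residues = []
    for ri in range(0, len(pts), 4):
        block = pts[ri:ri + 4]
        atoms = [Atom(names[k], _ELEMENTS[names[k]], block[k]) for k in range(len(block))]
        residues.append(Residue((chain_id, start_resnum + ri // 4, ""), "GLY", "G", atoms))
    return Chain(chain_id, residues)


@dataclass
class ScenarioSpec:
    """Parameters of one synthetic collision scenario.

    ``displacement`` moves the S domain relative to the R domain position in
    the frame of the first primary instance, so it directly controls the
    overlap after superposition. ``perturbation_*`` applies a rigid motion to
    the whole second structure (undone by superposition); ``noise_sigma``
    jitters the second primary instance's atoms and therefore sets the
    residual RMSD. ``bend`` kinks the second primary instance by 90 degrees
    at its midpoint, which defeats rigid superposition (RMSD gate fails).
    """
    n_residues_primary: int = 40
    interface_size_target: int = 6
    interface_overlap_target: int = 0  # shared P residues between the two interfaces
    displacement: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    perturbation_angle: float = 30.0  # degrees, about z through the centroid
    perturbation_shift: Tuple[float, float, float] = (20.0, -15.0, 8.0)
    noise_sigma: float = 0.05  # A, per-coordinate jitter on instance 2
    extra_residues: int = 0  # appended to instance 2 (drives the length gate)
    bend: bool = False
    seed: int = 42

    def __post_init__(self):
        if self.n_residues_primary <= 0 or self.interface_size_target <= 0:
            raise ValueError("counts must be positive")


@dataclass
class GroundTruth:
    """Gate outcomes certified by construction (only certain gates are listed)."""
    expected_flags: Dict[str, bool]
    expected_is_collision: bool
    interface_pr: Set[int]  # P residue indices (0-based) at the P-R interface
    interface_ps: Set[int]
    expected_rmsd: float
    lens_lower_bound: float


def _rigid(coords: np.ndarray, angle_deg: float, shift: Sequence[float],
           pivot: np.ndarray) -> np.ndarray:
    a = math.radians(angle_deg)
    rot = np.array([[math.cos(a), -math.sin(a), 0.0],
                    [math.sin(a), math.cos(a), 0.0],
                    [0.0, 0.0, 1.0]])
    return (coords - pivot) @ rot.T + pivot + np.asarray(shift, dtype=float)


def _transform_chain(chain: Chain, angle_deg: float, shift, pivot) -> None:
    for res in chain.residues:
        for atom in res.atoms:
            atom.position = _rigid(atom.position[None, :], angle_deg, shift, pivot)[0]


def _contact_chain(chain_p: Chain, residue_idx: Sequence[int], chain_id: str) -> List[Residue]:
    """One alanine per target residue, its N atom 4.6 A above the target CA.

    Atom heights are staggered so only the lowest atom of each alanine can
    reach the primary chain within a 5 A cutoff.
    """
    residues = []
    for n, idx in enumerate(residue_idx):
        ca = chain_p.residues[idx].ca.position
        base = ca + np.array([0.0, 0.0, CONTACT_HEIGHT])
        atoms = [
            Atom("N", "N", base),
            Atom("CA", "C", base + np.array([0.0, 0.0, 1.5])),
            Atom("C", "C", base + np.array([0.0, 0.5, 2.8])),
            Atom("O", "O", base + np.array([0.0, 1.5, 3.4])),
            Atom("CB", "C", base + np.array([0.0, -1.0, 2.6])),
        ]
        residues.append(Residue((chain_id, n + 1, ""), "ALA", "A", atoms))
    return residues


def _brute_force_interface(chain_a: Chain, chain_b: Chain, cutoff: float = 5.0
                           ) -> Set[int]:
    """Indices of chain_a residues with any atom within cutoff of chain_b (plain loops)."""
    coords_b = np.array([a.position for r in chain_b.residues for a in r.atoms])
    hits: Set[int] = set()
    for i, res in enumerate(chain_a.residues):
        for atom in res.atoms:
            d2 = ((coords_b - atom.position) ** 2).sum(axis=1)
            if (d2 <= cutoff * cutoff).any():
                hits.add(i)
                break
    return hits


def _kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Reference RMSD by SVD, independent of the quaternion solver."""
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    u, s, vt = np.linalg.svd(ac.T @ bc)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    return float(np.sqrt(((bc @ rot.T - ac) ** 2).sum() / len(a)))


# a fixed, glycine-free sequence pool for primary chains
_SEQ_POOL = "AVLIMFWPSTCYNQDEKRH" * 10


def make_collision_scenario(spec: ScenarioSpec,
                            ) -> Tuple[StructureModel, StructureModel, GroundTruth]:
    """Build the P-R and P-S structures plus certified ground truth."""
    n = spec.n_residues_primary
    k = spec.interface_size_target
    shared = spec.interface_overlap_target
    if k > n or shared > k:
        raise ValueError("infeasible interface targets")
    # P-R interface block starts at 2; P-S block overlaps it by `shared`
    # residues or is separated by a 3-residue guard band.
    start_r = 2
    start_s = start_r + k - shared if shared > 0 else start_r + k + 3
    if start_s + k > n - 2:
        raise ValueError("primary chain too short for the requested interfaces")
    rng = np.random.default_rng(spec.seed)

    seq = _SEQ_POOL[:n]
    chain_p1 = make_ideal_chain(seq, "A")
    set_r = list(range(start_r, start_r + k))
    set_s = list(range(start_s, start_s + k))

    # structure 1: P + R
    r_contacts = _contact_chain(chain_p1, set_r, "B")
    r_center = chain_p1.residues[set_r[len(set_r) // 2]].ca.position + \
        np.array([0.0, 0.0, BLOB_CENTER_Z])
    chain_r = Chain("B", r_contacts + make_domain_chain(
        r_center, "B", start_resnum=len(r_contacts) + 1).residues)
    model_pr = StructureModel("syn1", 1, [chain_p1, chain_r])

    # structure 2: P' + S, in its own (perturbed) frame
    seq2 = seq + _SEQ_POOL[n:n + spec.extra_residues]
    chain_p2 = make_ideal_chain(seq2, "A")
    if spec.bend:
        mid = n // 2
        pivot = chain_p2.residues[mid].ca.position.copy()
        for res in chain_p2.residues[mid:]:
            for atom in res.atoms:
                rel = atom.position - pivot
                atom.position = pivot + np.array([rel[1], -rel[0], rel[2]])  # 90 deg about z
    if spec.noise_sigma > 0:
        for res in chain_p2.residues:
            for atom in res.atoms:
                atom.position = atom.position + rng.normal(0.0, spec.noise_sigma, 3)

    s_contacts = _contact_chain(chain_p2, set_s, "B")
    s_center = r_center + np.asarray(spec.displacement, dtype=float)
    chain_s = Chain("B", s_contacts + make_domain_chain(
        s_center, "B", start_resnum=len(s_contacts) + 1).residues)
    model_ps = StructureModel("syn2", 1, [chain_p2, chain_s])

    # ground truth, before the frame perturbation (which superposition undoes)
    gt_iface_pr = _brute_force_interface(chain_p1, chain_r)
    gt_iface_ps = _brute_force_interface(chain_p2, chain_s)
    n_common = len(set(range(n)) & gt_iface_pr & gt_iface_ps)
    gt_r_side = _brute_force_interface(chain_r, chain_p1)
    gt_s_side = _brute_force_interface(chain_s, chain_p2)

    ca1 = np.array([r.ca.position for r in chain_p1.residues])
    ca2 = np.array([r.ca.position for r in chain_p2.residues[:n]])
    expected_rmsd = _kabsch_rmsd(ca1, ca2)

    d = float(np.linalg.norm(spec.displacement))
    r_cov = covered_ball_radius()
    lens_lb = lens_volume(r_cov, r_cov, d)
    blob_gap = d - 2 * (R_BLOB + 1.7 + 1.5)  # surface gap incl. vdW + probe
    if lens_lb < 2400.0 and blob_gap < 10.0:
        raise ValueError("displacement lies in the ambiguous overlap regime; "
                         "use |d| <= 4 (collision) or |d| >= 38 (clear)")
    colliding = lens_lb >= 2400.0

    flags = {
        "min_interface_size": min(len(gt_iface_pr), len(gt_iface_ps),
                                  len(gt_r_side), len(gt_s_side)) >= 5,
        "interfaces_distinct": n_common == 0,
        "len_diff_ok": spec.extra_residues <= 15,
        "aligned_len_ok": n >= 30,
        "rmsd_ok": expected_rmsd < 7.0,
    }
    if all(flags.values()):
        flags["overlap_ok_ses"] = colliding
        flags["overlap_ok_sas"] = colliding
    truth = GroundTruth(
        expected_flags=flags,
        expected_is_collision=all(flags.values()) and colliding,
        interface_pr=gt_iface_pr, interface_ps=gt_iface_ps,
        expected_rmsd=expected_rmsd, lens_lower_bound=lens_lb,
    )

    # finally move structure 2 into its own frame
    pivot = np.array([r.ca.position for r in chain_p2.residues]).mean(axis=0)
    for chain in model_ps.chains:
        _transform_chain(chain, spec.perturbation_angle, spec.perturbation_shift, pivot)
    return model_pr, model_ps, truth


def scenario_collection(model_pr: StructureModel, model_ps: StructureModel,
                        ) -> StructureCollection:
    """Wrap the two scenario structures with the accessions the screen needs."""
    return StructureCollection(
        models=[model_pr, model_ps],
        accession_map={
            (model_pr.entry_id, "A"): "PRIM1", (model_pr.entry_id, "B"): "SECR1",
            (model_ps.entry_id, "A"): "PRIM1", (model_ps.entry_id, "B"): "SECS1",
        })


def make_ensemble(n_scenarios: int = 50, seed: int = 42) -> List[
        Tuple[ScenarioSpec, StructureModel, StructureModel, GroundTruth]]:
    """Seeded ensemble mixing colliding, separated and gate-failing scenarios.

    Roughly 60% are clean collisions with varying displacement (0-4 A), the
    rest exercise each failure mode: far displacement, shared interface
    residues, undersized interfaces, excess length difference, short chains
    and bent (high-RMSD) instances.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_scenarios):
        mode = i % 10
        kwargs = dict(seed=int(rng.integers(0, 2**31 - 1)))
        if mode < 6:  # collision, varying displacement direction and magnitude
            d = float(rng.uniform(0.0, 4.0))
            theta = float(rng.uniform(0.0, 2 * math.pi))
            kwargs["displacement"] = (d * math.cos(theta), d * math.sin(theta), 0.0)
        elif mode == 6:  # clearly separated domains
            kwargs["displacement"] = (float(rng.uniform(38.0, 50.0)), 0.0, 0.0)
        elif mode == 7:  # overlapping interfaces
            kwargs["interface_overlap_target"] = int(rng.integers(1, 3))
        elif mode == 8:  # undersized interface
            kwargs["interface_size_target"] = 4
        else:  # refinement-gate failures, alternating
            which = (i // 10) % 3
            if which == 0:
                kwargs["extra_residues"] = int(rng.integers(16, 25))
            elif which == 1:
                kwargs["n_residues_primary"] = 25
                kwargs["interface_size_target"] = 5
            else:
                kwargs["bend"] = True
        spec = ScenarioSpec(**kwargs)
        model_pr, model_ps, truth = make_collision_scenario(spec)
        out.append((spec, model_pr, model_ps, truth))
    return out
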