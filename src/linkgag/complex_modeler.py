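"""Restraint-driven modeling of oligosaccharide/Link-module complexes.

The receptor is held rigid (its coordinates are never modified by any
operation here); the ligand is an oligosaccharide conformer with free
glycosidic torsions and a free rigid-body placement. Models are produced by
seeded simulated annealing over (torsions + rigid body) against an objective
combining

* restraint energy — a 3.5 A ring-stacking restraint between a sugar ring
  and an aromatic/imidazole ring (flat-bottomed quadratic in the centroid
  distance plus a penalty when the ring planes tilt past a maximum angle),
  and flat-bottomed upper-bound distance restraints (e.g. the ring-4
  N-acetyl methyl carbon to the Ile side-chain terminal carbon);
* a steric clash penalty (quadratic overlap below a scaled vdW sum);
* the Phi/Psi map energy of every glycosidic linkage.

An annealed ensemble is then filtered on geometry sanity (glycosidic bond
lengths, residual clashes, restraint satisfaction) and on the map-based
favored/disfavored verdict of every linkage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence as Seq

import gemmi
import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .glycan_builder import (
    VDW_RADIUS,
    GlycanConformer,
    GlycanSequence,
    build_conformer,
    kabsch,
)
from .torsion_maps import TorsionMap, classify_linkages, map_energy, DEFAULT_CUTOFF

DEFAULT_CLASH_SCALE = 0.7
DEFAULT_CONTACT_CUTOFF = 4.0  # Angstrom
RESTRAINT_CONVERGED = 0.1  # kcal/mol-equivalent
GLYCOSIDIC_BOND_TOL = 0.05  # Angstrom


class ModelingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# receptor


@dataclass
class Receptor:
    """Immutable rigid receptor; coordinates are write-protected."""

    atom_names: list[str]
    res_names: list[str]
    res_nums: list[int]
    coords: np.ndarray
    elements: list[str]

    def __post_init__(self):
        self.coords = np.array(self.coords, dtype=float)
        self.coords.setflags(write=False)

    @property
    def radii(self) -> np.ndarray:
        return np.array([VDW_RADIUS.get(e, 1.7) for e in self.elements])

    def checksum(self) -> float:
        return float(np.sum(self.coords * np.arange(1, self.coords.size + 1).reshape(self.coords.shape)))

    def atom_index(self, res_num: int, atom_name: str) -> int:
        for i, (rn, an) in enumerate(zip(self.res_nums, self.atom_names)):
            if rn == res_num and an == atom_name:
                return i
        raise ModelingError(f"receptor has no atom {atom_name!r} in residue {res_num}")

    def atom(self, res_num: int, atom_name: str) -> np.ndarray:
        return self.coords[self.atom_index(res_num, atom_name)]

    def ring_atoms(self, res_num: int, names: Seq[str]) -> np.ndarray:
        return np.array([self.atom(res_num, n) for n in names])


def _receptor_from_model(model: "gemmi.Model") -> Receptor:
    names, resnames, resnums, coords, elements = [], [], [], [], []
    for chain in model:
        for res in chain:
            for at in res:
                if at.element.name == "H":
                    continue
                names.append(at.name)
                resnames.append(res.name)
                resnums.append(res.seqid.num)
                coords.append([at.pos.x, at.pos.y, at.pos.z])
                elements.append(at.element.name)
    return Receptor(names, resnames, resnums, np.array(coords), elements)


def load_receptor(path, model_index: int = 0,
                  restraints: Optional[list] = None) -> Receptor:
    """Load one MODEL of a (possibly multi-model) PDB file as a Receptor.

    When ``restraints`` is given, every receptor atom they reference must be
    present; missing atoms are reported together in the error message.
    """
    st = gemmi.read_structure(str(path))
    if not 0 <= model_index < len(st):
        raise ModelingError(
            f"model index {model_index} out of range: file has {len(st)} model(s)"
        )
    receptor = _receptor_from_model(st[model_index])
    if restraints:
        validate_receptor(receptor, restraints)
    return receptor


def load_receptor_models(path, restraints: Optional[list] = None) -> list[Receptor]:
    """All MODELs of a multi-model PDB (e.g. a 20-member NMR ensemble)."""
    st = gemmi.read_structure(str(path))
    out = [_receptor_from_model(m) for m in st]
    if restraints:
        for r in out:
            validate_receptor(r, restraints)
    return out


def validate_receptor(receptor: Receptor, restraints: list) -> None:
    missing = []
    for rst in restraints:
        for res_num, atom_name in rst.receptor_atom_specs():
            try:
                receptor.atom_index(res_num, atom_name)
            except ModelingError:
                missing.append(f"{res_num}/{atom_name}")
    if missing:
        raise ModelingError(
            "receptor is missing restraint atoms: " + ", ".join(missing)
        )


# ---------------------------------------------------------------------------
# restraints


def _plane_normal(points: np.ndarray) -> np.ndarray:
    x = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(x)
    return vt[2]


@dataclass
class StackingRestraint:
    """Face-to-face stacking of a sugar ring on a receptor aromatic ring.

    Zero energy when the ring-centroid distance is at or below ``target``
    and the angle between ring normals is at or below ``max_angle_deg``.
    """

    receptor_res: int
    receptor_ring_atoms: tuple[str, ...]
    ligand_ring: int
    target: float = 3.5
    max_angle_deg: float = 30.0
    k: float = 1.0  # kcal/(mol A^2)
    k_angle: float = 10.0  # kcal/(mol rad^2)

    def receptor_atom_specs(self):
        return [(self.receptor_res, n) for n in self.receptor_ring_atoms]

    def energy(self, receptor: Receptor, ligand: GlycanConformer) -> float:
        ring = receptor.ring_atoms(self.receptor_res, self.receptor_ring_atoms)
        rc = ring.mean(axis=0)
        rn = _plane_normal(ring)
        lc = ligand.ring_centroid(self.ligand_ring)
        ln = ligand.ring_normal(self.ligand_ring)
        d = float(np.linalg.norm(lc - rc))
        cosang = abs(float(np.dot(rn, ln)))
        ang = math.degrees(math.acos(min(1.0, cosang)))
        e = self.k * max(0.0, d - self.target) ** 2
        e += self.k_angle * max(0.0, math.radians(ang - self.max_angle_deg)) ** 2
        return e


@dataclass
class DistanceRestraint:
    """Flat-bottomed upper-bound distance between one atom on each side."""

    receptor_res: int
    receptor_atom: str
    ligand_ring: int
    ligand_atom: str
    bound: float = 4.5
    k: float = 1.0

    def receptor_atom_specs(self):
        return [(self.receptor_res, self.receptor_atom)]

    def energy(self, receptor: Receptor, ligand: GlycanConformer) -> float:
        p = receptor.atom(self.receptor_res, self.receptor_atom)
        q = ligand.atom(self.ligand_ring - 1, self.ligand_atom)
        d = float(np.linalg.norm(p - q))
        return self.k * max(0.0, d - self.bound) ** 2


HIS_RING_ATOMS = ("CG", "ND1", "CD2", "CE1", "NE2")
TYR_RING_ATOMS = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")


def refinement_restraints() -> list:
    """The two structural restraints added by the refinement: a 3.5 A stack
    of sugar ring 1 on the His45 imidazole and an upper bound between the
    ring-4 N-acetyl methyl carbon and the Ile61 side-chain terminal carbon
    (4.5 A, a typical methyl-methyl hydrophobic contact; configurable)."""
    return [
        StackingRestraint(receptor_res=45, receptor_ring_atoms=HIS_RING_ATOMS,
                          ligand_ring=1),
        DistanceRestraint(receptor_res=61, receptor_atom="CD1",
                          ligand_ring=4, ligand_atom="C8"),
    ]


def groove_restraints() -> list:
    """The groove interactions the octasaccharide model was originally built
    on: aromatic stacks of rings 5 and 6 on Tyr59 and Tyr78, the Lys11 and
    Arg81 salt bridges to the ring-3 and ring-7 carboxylates, and the Tyr12
    hydrogen bond to the ring-4 C4 hydroxyl."""
    return [
        StackingRestraint(receptor_res=59, receptor_ring_atoms=TYR_RING_ATOMS,
                          ligand_ring=5, target=4.0),
        StackingRestraint(receptor_res=78, receptor_ring_atoms=TYR_RING_ATOMS,
                          ligand_ring=6, target=4.0),
        DistanceRestraint(receptor_res=11, receptor_atom="NZ",
                          ligand_ring=3, ligand_atom="O6A", bound=4.0),
        DistanceRestraint(receptor_res=81, receptor_atom="NH1",
                          ligand_ring=7, ligand_atom="O6A", bound=4.0),
        DistanceRestraint(receptor_res=12, receptor_atom="OH",
                          ligand_ring=4, ligand_atom="O4", bound=3.5),
    ]


def default_restraints() -> list:
    """Full modeling restraint set: the original groove interactions plus
    the two refinement restraints."""
    return groove_restraints() + refinement_restraints()


def restraint_energy(receptor: Receptor, ligand: GlycanConformer,
                     restraints: list) -> float:
    """Sum of flat-bottomed quadratic penalties over all restraints."""
    return float(sum(r.energy(receptor, ligand) for r in restraints))


# ---------------------------------------------------------------------------
# clashes and contacts


def _restrained_pairs(receptor: Receptor, ligand: GlycanConformer,
                      restraints: list) -> set[tuple[int, int]]:
    pairs = set()
    for rst in restraints:
        rec_idx = [receptor.atom_index(rn, an) for rn, an in rst.receptor_atom_specs()]
        if isinstance(rst, StackingRestraint):
            lig_idx = list(ligand.heavy_indices_of_ring(rst.ligand_ring))
        else:
            lig_idx = [ligand.residue_atoms[rst.ligand_ring - 1][rst.ligand_atom]]
        for i in rec_idx:
            for j in lig_idx:
                pairs.add((i, int(j)))
    return pairs


def clash_score(receptor: Receptor, ligand: GlycanConformer,
                scale: float = DEFAULT_CLASH_SCALE,
                restraints: Optional[list] = None,
                tree: Optional[cKDTree] = None) -> tuple[int, float]:
    """Count and penalize atom pairs closer than scale x (r_i + r_j).

    Pairs participating in a restraint are excluded. Returns
    (clash count, quadratic overlap penalty).
    """
    rr = receptor.radii
    lr = ligand.radii
    exclude = _restrained_pairs(receptor, ligand, restraints) if restraints else set()
    if tree is None:
        tree = cKDTree(receptor.coords)
    dmax = scale * (rr.max() + lr.max())
    count = 0
    penalty = 0.0
    neighbor_lists = tree.query_ball_point(ligand.coords, dmax)
    for j, neighbors in enumerate(neighbor_lists):
        for i in neighbors:
            if (i, j) in exclude:
                continue
            d = float(np.linalg.norm(receptor.coords[i] - ligand.coords[j]))
            lim = scale * (rr[i] + lr[j])
            if d < lim:
                count += 1
                penalty += (lim - d) ** 2
    return count, penalty


def ring_contacts(receptor: Receptor, ligand: GlycanConformer,
                  cutoff: float = DEFAULT_CONTACT_CUTOFF) -> tuple[list[bool], int]:
    """Per-ring protein contact flags and the number of rings in contact.

    A ring contacts the receptor when any of its heavy atoms lies within
    ``cutoff`` of any receptor heavy atom.
    """
    tree = cKDTree(receptor.coords)
    flags = []
    for ring in range(1, len(ligand.sequence) + 1):
        idx = ligand.heavy_indices_of_ring(ring)
        d, _ = tree.query(ligand.coords[idx], k=1)
        flags.append(bool(np.min(d) <= cutoff))
    return flags, sum(flags)


# ---------------------------------------------------------------------------
# models


@dataclass
class ComplexModel:
    """A posed ligand on a fixed receptor with its score components."""

    receptor: Receptor
    ligand: GlycanConformer
    scores: dict[str, float] = field(default_factory=dict)
    clash_count: int = 0
    converged: bool = True
    accept: bool = False
    seed: Optional[int] = None
    rejection_reason: Optional[str] = None

    @property
    def total_score(self) -> float:
        return float(sum(self.scores.values()))


@dataclass
class AnnealConfig:
    """Schedule constants for the torsion/rigid-body simulated annealing."""

    n_steps: int = 800
    t_start: float = 2.0
    t_end: float = 0.01
    torsion_step_deg: float = 8.0
    rot_step_deg: float = 3.0
    trans_step: float = 0.3
    clash_weight: float = 10.0
    #: the objective scores clashes at clash_margin x the filter scale, so
    #: optimized models clear the acceptance boundary with room to spare
    #: (the quadratic penalty has zero gradient exactly at the limit)
    clash_margin: float = 1.05
    polish: bool = True
    polish_maxfev: int = 3000


def _initial_placements(receptor: Receptor, ligand: GlycanConformer,
                        restraints: list) -> list[tuple[np.ndarray, np.ndarray]]:
    """Candidate restraint-guided rigid placements (rotation, translation).

    Matches the stacked ligand ring onto the receptor ring at the target
    distance along the receptor ring normal — one candidate per normal side,
    since the binding face is not known a priori — and pulls any
    distance-restraint ligand atoms toward their receptor anchors. The
    caller keeps whichever candidate scores best.
    """
    rec_center = receptor.coords.mean(axis=0)
    stack_targets = []
    for side in (1.0, -1.0):
        for rst in restraints:
            if isinstance(rst, StackingRestraint):
                ring = receptor.ring_atoms(rst.receptor_res, rst.receptor_ring_atoms)
                rn = side * _plane_normal(ring)
                stack_targets.append(ring.mean(axis=0) + rst.target * rn)
    candidates = []
    for side in (1.0, -1.0):
        src, dst = [], []
        for rst in restraints:
            if isinstance(rst, StackingRestraint):
                ring = receptor.ring_atoms(rst.receptor_res, rst.receptor_ring_atoms)
                rc = ring.mean(axis=0)
                rn = side * _plane_normal(ring)
                lc = ligand.ring_centroid(rst.ligand_ring)
                ln = ligand.ring_normal(rst.ligand_ring)
                src.append(lc)
                dst.append(rc + rst.target * rn)
                src.append(lc + 3.0 * ln)
                dst.append(rc + (rst.target + 3.0) * rn)
            else:
                anchor = receptor.atom(rst.receptor_res, rst.receptor_atom)
                # aim just inside the bound, toward the binding face when a
                # stacking site defines one
                if stack_targets:
                    direction = stack_targets[0] - anchor
                else:
                    direction = rec_center - anchor
                nrm = np.linalg.norm(direction)
                direction = (direction / nrm if nrm > 1e-9
                             else np.array([0.0, 0.0, 1.0]))
                src.append(ligand.atom(rst.ligand_ring - 1, rst.ligand_atom))
                dst.append(anchor + 0.8 * rst.bound * direction)
        if len(src) < 3:
            src.append(ligand.coords.mean(axis=0))
            dst.append(rec_center + side * np.array([0.0, 0.0, 15.0]))
        candidates.append(kabsch(np.array(src), np.array(dst)))
    return candidates


def _pose(base: GlycanConformer, rotvec: np.ndarray, trans: np.ndarray,
          r0: np.ndarray, t0: np.ndarray) -> GlycanConformer:
    r = Rotation.from_rotvec(rotvec).as_matrix() @ r0
    t = trans + Rotation.from_rotvec(rotvec).as_matrix() @ t0
    return base.transformed(r, t)


def anneal_model(receptor: Receptor, sequence: GlycanSequence, restraints: list,
                 maps: dict[str, TorsionMap], seed: int,
                 config: Optional[AnnealConfig] = None,
                 initial_torsions=None) -> ComplexModel:
    """Seeded simulated annealing over ligand torsions and rigid placement.

    Deterministic for a given seed. Returns the best model found; if the
    final restraint energy exceeds the convergence threshold the model is
    returned flagged (``converged=False``), never silently dropped.
    """
    cfg = config or AnnealConfig()
    rng = np.random.default_rng(seed)
    n_link = len(sequence) - 1
    if initial_torsions is None:
        torsions = np.array(
            [maps[l].minimum_location() for l in sequence.linkages], dtype=float
        )
    else:
        torsions = np.array(initial_torsions, dtype=float)
    tree = cKDTree(receptor.coords)

    base = build_conformer(sequence, torsions)
    placements = _initial_placements(receptor, base, restraints)
    r0, t0 = placements[0]

    # torsion-keyed cache: rigid-body moves and rigid line searches reuse
    # the previously built conformer
    _cache: dict = {"key": None, "conf": None}

    def base_conformer(tors: np.ndarray) -> GlycanConformer:
        key = tors.tobytes()
        if _cache["key"] != key:
            _cache["key"] = key
            _cache["conf"] = build_conformer(sequence, tors.reshape(n_link, 2))
        return _cache["conf"]

    def objective(tors: np.ndarray, rotvec: np.ndarray, trans: np.ndarray) -> float:
        conf = _pose(base_conformer(tors), rotvec, trans, r0, t0)
        e = restraint_energy(receptor, conf, restraints)
        _, pen = clash_score(receptor, conf,
                             scale=DEFAULT_CLASH_SCALE * cfg.clash_margin,
                             restraints=restraints, tree=tree)
        e += cfg.clash_weight * pen
        # the build realizes requested torsions exactly, so the map term can
        # be evaluated on the parameters directly
        for link, (phi, psi) in zip(sequence.linkages, tors.reshape(n_link, 2)):
            e += map_energy(maps[link], phi, psi)
        return e

    state_t = torsions.reshape(-1).copy()
    state_rv = np.zeros(3)
    state_tr = np.zeros(3)
    chosen = None
    for rr, tt in placements:
        r0, t0 = rr, tt
        # rigid pre-fit on the smooth restraint term alone before scoring
        # the full objective: the Kabsch guess only matches anchor points
        # approximately

        def rigid_restraint(x):
            conf = _pose(base, x[:3], x[3:], r0, t0)
            return restraint_energy(receptor, conf, restraints)

        pre = minimize(rigid_restraint, np.zeros(6), method="Powell",
                       options={"maxfev": 800, "xtol": 1e-4, "ftol": 1e-8})
        rv, tr = pre.x[:3].copy(), pre.x[3:].copy()
        e = objective(state_t, rv, tr)
        if chosen is None or e < chosen[0]:
            chosen = (e, rr, tt, rv, tr)
    e_cur, r0, t0, state_rv, state_tr = chosen
    init_rv, init_tr = state_rv.copy(), state_tr.copy()
    best = (e_cur, state_t.copy(), state_rv.copy(), state_tr.copy())

    alpha = (cfg.t_end / cfg.t_start) ** (1.0 / max(1, cfg.n_steps - 1))
    temp = cfg.t_start
    for _ in range(cfg.n_steps):
        cand_t = state_t.copy()
        cand_rv = state_rv.copy()
        cand_tr = state_tr.copy()
        if rng.random() < 0.5 and n_link > 0:
            k = rng.integers(0, n_link)
            cand_t[2 * k: 2 * k + 2] += rng.normal(0.0, cfg.torsion_step_deg, 2)
        else:
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            cand_rv = cand_rv + axis * math.radians(rng.normal(0.0, cfg.rot_step_deg))
            cand_tr = cand_tr + rng.normal(0.0, cfg.trans_step, 3)
        e_new = objective(cand_t, cand_rv, cand_tr)
        if e_new <= e_cur or rng.random() < math.exp(-(e_new - e_cur) / temp):
            state_t, state_rv, state_tr, e_cur = cand_t, cand_rv, cand_tr, e_new
            if e_cur < best[0]:
                best = (e_cur, state_t.copy(), state_rv.copy(), state_tr.copy())
        temp *= alpha

    e_best, bt, brv, btr = best

    def flat(x):
        return objective(x[: 2 * n_link], x[2 * n_link: 2 * n_link + 3],
                         x[2 * n_link + 3:])

    def polish(x0):
        return minimize(flat, x0, method="Powell",
                        options={"maxfev": cfg.polish_maxfev, "xtol": 1e-5,
                                 "ftol": 1e-9})

    if cfg.polish:
        res = polish(np.concatenate([bt, brv, btr]))
        if res.fun < e_best:
            e_best = float(res.fun)
            bt = res.x[: 2 * n_link]
            brv = res.x[2 * n_link: 2 * n_link + 3]
            btr = res.x[2 * n_link + 3:]

    def evaluate(tors, rotvec, trans):
        conf = build_conformer(sequence, tors.reshape(n_link, 2))
        conf = _pose(conf, rotvec, trans, r0, t0)
        e_rst = restraint_energy(receptor, conf, restraints)
        n_clash, pen = clash_score(receptor, conf, restraints=restraints,
                                   tree=tree)
        return conf, e_rst, n_clash, pen

    conf, e_rst, n_clash, pen = evaluate(bt, brv, btr)
    if cfg.polish and (e_rst >= RESTRAINT_CONVERGED or n_clash > 0):
        # the annealed basin failed the acceptance rules: re-polish from the
        # restraint-guided starting pose and keep the better endpoint
        res = polish(np.concatenate([torsions.reshape(-1), init_rv, init_tr]))
        if res.fun < e_best:
            e_best = float(res.fun)
            bt = res.x[: 2 * n_link]
            brv = res.x[2 * n_link: 2 * n_link + 3]
            btr = res.x[2 * n_link + 3:]
            conf, e_rst, n_clash, pen = evaluate(bt, brv, btr)
    e_map = 0.0
    from .glycan_builder import measure_torsions
    for link, (phi, psi) in zip(sequence.linkages, measure_torsions(conf)):
        e_map += map_energy(maps[link], phi, psi)
    return ComplexModel(
        receptor=receptor,
        ligand=conf,
        scores={"restraint": e_rst, "clash": cfg.clash_weight * pen, "map": e_map},
        clash_count=n_clash,
        converged=e_rst < RESTRAINT_CONVERGED,
        seed=seed,
    )


def filter_model(model: ComplexModel, maps: dict[str, TorsionMap],
                 cutoff: float = DEFAULT_CUTOFF) -> ComplexModel:
    """Apply the geometry-sanity and Phi/Psi acceptance rules to one model.

    A torsion-space build cannot produce the distorted covalent bonds that a
    Cartesian refinement can, so the equivalent sanity check is the deviation
    of each glycosidic bond length from its template value, together with the
    residual clash count and restraint convergence.
    """
    seq = model.ligand.sequence
    from .glycan_builder import TEMPLATES
    dev = []
    for i, link in enumerate(seq.linkages):
        template_len = TEMPLATES[seq.residues[i]].bond_length("C1", "O1")
        dev.append(abs(model.ligand.glycosidic_bond_lengths()[i] - template_len))
    reason = None
    if max(dev) > GLYCOSIDIC_BOND_TOL:
        reason = "distorted-bond"
    elif model.clash_count > 0:
        reason = "clash"
    elif not model.converged:
        reason = "restraint-unsatisfied"
    else:
        verdict = classify_linkages(model.ligand, maps, cutoff=cutoff)
        if not verdict.accept:
            reason = "unfavored-torsion"
    model.rejection_reason = reason
    model.accept = reason is None
    return model


def generate_and_filter_ensemble(
    receptors: Seq[Receptor],
    sequence: GlycanSequence,
    restraints: list,
    maps: dict[str, TorsionMap],
    n_models: int = 20,
    cutoff: float = DEFAULT_CUTOFF,
    base_seed: int = 0,
    config: Optional[AnnealConfig] = None,
) -> tuple[list[ComplexModel], list[dict]]:
    """Anneal ``n_models`` seeded models (cycling the receptor ensemble) and
    keep those passing the geometry and Phi/Psi filters.

    Returns (accepted models, per-model report rows). An all-rejected run
    returns an empty accepted list — the report carries the reasons.
    """
    accepted: list[ComplexModel] = []
    report: list[dict] = []
    for k in range(int(n_models)):
        receptor = receptors[k % len(receptors)]
        seed = base_seed + k
        model = anneal_model(receptor, sequence, restraints, maps, seed,
                             config=config)
        model = filter_model(model, maps, cutoff=cutoff)
        report.append(
            {
                "seed": seed,
                "receptor_member": k % len(receptors),
                "accepted": model.accept,
                "reason": model.rejection_reason or "",
                "restraint": model.scores["restraint"],
                "clash_count": model.clash_count,
                "map": model.scores["map"],
            }
        )
        if model.accept:
            accepted.append(model)
    return accepted, report


def read_ensemble_pdb(path, ligand_chain: str = "X"
                      ) -> list[tuple[Receptor, GlycanConformer]]:
    """Read complexes written by :func:`write_ensemble_pdb`, one per MODEL.

    Allows the acceptance rules (clashes, restraints, favored torsions) to be
    re-checked independently from the saved output alone.
    """
    from .glycan_builder import PDB_RESNAME_INV, GlycanSequence

    st = gemmi.read_structure(str(path))
    out = []
    for model in st:
        rec_names, rec_resnames, rec_resnums, rec_coords, rec_elements = \
            [], [], [], [], []
        residues: list[str] = []
        coords, names, elems, residx = [], [], [], []
        residue_atoms: list[dict[str, int]] = []
        for chain in model:
            for res in chain:
                if chain.name == ligand_chain:
                    residues.append(PDB_RESNAME_INV[res.name])
                    table: dict[str, int] = {}
                    for at in res:
                        table[at.name] = len(coords)
                        coords.append([at.pos.x, at.pos.y, at.pos.z])
                        names.append(at.name)
                        elems.append(at.element.name)
                        residx.append(len(residues) - 1)
                    residue_atoms.append(table)
                else:
                    for at in res:
                        rec_names.append(at.name)
                        rec_resnames.append(res.name)
                        rec_resnums.append(res.seqid.num)
                        rec_coords.append([at.pos.x, at.pos.y, at.pos.z])
                        rec_elements.append(at.element.name)
        receptor = Receptor(rec_names, rec_resnames, rec_resnums,
                            np.array(rec_coords), rec_elements)
        ligand = GlycanConformer(
            sequence=GlycanSequence(tuple(residues)),
            coords=np.array(coords),
            atom_names=names,
            atom_elements=elems,
            atom_residue=residx,
            residue_atoms=residue_atoms,
        )
        out.append((receptor, ligand))
    return out


def write_ensemble_pdb(models: Seq[ComplexModel], path,
                       ligand_chain: str = "X") -> None:
    """Write receptor + ligand complexes, one MODEL per accepted structure."""
    from .glycan_builder import PDB_RESNAME

    st = gemmi.Structure()
    st.name = "complex-ensemble"
    for mi, model in enumerate(models, start=1):
        gm = gemmi.Model(str(mi))
        ch = gemmi.Chain("A")
        rec = model.receptor
        res_map: dict[int, gemmi.Residue] = {}
        for name, rname, rnum, xyz, el in zip(
            rec.atom_names, rec.res_names, rec.res_nums, rec.coords, rec.elements
        ):
            if rnum not in res_map:
                r = gemmi.Residue()
                r.name = rname
                r.seqid = gemmi.SeqId(rnum, " ")
                res_map[rnum] = r
            at = gemmi.Atom()
            at.name = name
            at.element = gemmi.Element(el)
            at.pos = gemmi.Position(*xyz)
            res_map[rnum].add_atom(at)
        for rnum in sorted(res_map):
            ch.add_residue(res_map[rnum])
        gm.add_chain(ch)
        lig_ch = gemmi.Chain(ligand_chain)
        lig = model.ligand
        for i, resname in enumerate(lig.sequence.residues):
            r = gemmi.Residue()
            r.name = PDB_RESNAME[resname]
            r.seqid = gemmi.SeqId(i + 1, " ")
            for name, idx in lig.residue_atoms[i].items():
                at = gemmi.Atom()
                at.name = name
                at.element = gemmi.Element(lig.atom_elements[idx])
                at.pos = gemmi.Position(*lig.coords[idx])
                r.add_atom(at)
            lig_ch.add_residue(r)
        gm.add_chain(lig_ch)
        st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))
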