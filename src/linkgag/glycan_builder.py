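"""Torsion-parameterized construction of GAG oligosaccharides.

Hyaluronan (HA) is the alternating polymer [-4)GlcUA(beta1-3)GlcNAc(beta1-]
and unsulfated chondroitin replaces GlcNAc by GalNAc (the two HexNAcs differ
only in the orientation of the C4 hydroxyl: equatorial vs axial). Oligomers
are built from rigid idealized 4C1 chair templates joined by glycosidic
linkages whose geometry is fully described by the two dihedrals (Phi, Psi)
per linkage; ring-internal geometry never changes.

Dihedral convention (heavy atom), recorded as :data:`DIHEDRAL_CONVENTION`:

    Phi = O5(i) - C1(i) - Og - Cx(i+1)
    Psi = C1(i) - Og - Cx(i+1) - C(x+1)(i+1)

where ``Og`` is the glycosidic oxygen and ``x`` is 3 for a beta1,3 linkage
(donated by GlcUA) or 4 for a beta1,4 linkage (donated by a HexNAc).
Residue 1 is the non-reducing terminus throughout.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import gemmi
import numpy as np

DIHEDRAL_CONVENTION = "phi=O5-C1-Og-Cx;psi=C1-Og-Cx-C(x+1);heavy-atom"

#: glycosidic valence angle C1-Og-Cx, degrees
GLYCOSIDIC_ANGLE = 117.0

GLCUA = "GlcUA"
GLCNAC = "GlcNAc"
GALNAC = "GalNAc"

#: PDB residue names used on output (and recognized on input)
PDB_RESNAME = {GLCUA: "BDP", GLCNAC: "NAG", GALNAC: "A2G"}
PDB_RESNAME_INV = {v: k for k, v in PDB_RESNAME.items()}

VDW_RADIUS = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.10}

RING_ATOMS = ("O5", "C1", "C2", "C3", "C4", "C5")


class GlycanError(ValueError):
    """Raised for unparseable specifiers or inconsistent geometry requests."""


# ---------------------------------------------------------------------------
# vector helpers


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in [-180, 180)."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, _unit(b2))
    ang = math.degrees(math.atan2(np.dot(m1, n2), np.dot(n1, n2)))
    return wrap_angle(ang)


def wrap_angle(a: float) -> float:
    """Wrap an angle in degrees into [-180, 180)."""
    return (a + 180.0) % 360.0 - 180.0


def place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom d with |cd| = bond, angle(b,c,d) = angle, dihedral(a,b,c,d).

    Natural-extension-reference-frame construction, consistent with
    :func:`dihedral` (round trip is exact to numerical precision).
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = math.radians(angle_deg)
    chi = math.radians(dihedral_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-math.cos(theta), math.sin(theta) * math.cos(chi), -math.sin(theta) * math.sin(chi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def kabsch(moving: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (R, t) with R @ moving.T + t ~ target."""
    mc = moving.mean(axis=0)
    tc = target.mean(axis=0)
    h = (moving - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = tc - r @ mc
    return r, t


# ---------------------------------------------------------------------------
# templates


@dataclass(frozen=True)
class MonosaccharideTemplate:
    """Rigid idealized 4C1 pyranose with heavy atoms plus the acetamido methyl.

    ``atoms`` maps atom name -> (element, xyz). Hydroxyl hydrogens are not
    modeled; restraints and contact analysis use heavy atoms only.
    """

    name: str
    atoms: dict[str, tuple[str, np.ndarray]]

    def coords(self, names) -> np.ndarray:
        return np.array([self.atoms[n][1] for n in names])

    def bond_length(self, a: str, b: str) -> float:
        return float(np.linalg.norm(self.atoms[a][1] - self.atoms[b][1]))

    def bond_angle(self, a: str, b: str, c: str) -> float:
        u = _unit(self.atoms[a][1] - self.atoms[b][1])
        v = _unit(self.atoms[c][1] - self.atoms[b][1])
        return math.degrees(math.acos(np.clip(np.dot(u, v), -1.0, 1.0)))


def _substituent_dirs(pos: np.ndarray, nb1: np.ndarray, nb2: np.ndarray,
                      ring_normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(axial, equatorial) unit directions at a ring atom with two ring bonds."""
    u1 = _unit(nb1 - pos)
    u2 = _unit(nb2 - pos)
    bis = -_unit(u1 + u2)
    perp = _unit(np.cross(u1, u2))
    # two remaining ~tetrahedral directions
    d1 = _unit(bis + perp)
    d2 = _unit(bis - perp)
    if abs(np.dot(d1, ring_normal)) >= abs(np.dot(d2, ring_normal)):
        return d1, d2
    return d2, d1


def _build_template(name: str) -> MonosaccharideTemplate:
    # chair: ring atoms on a hexagon with alternating out-of-plane displacement
    radius, pucker = 1.45, 0.25
    order = RING_ATOMS  # O5, C1, C2, C3, C4, C5 around the cycle
    ring = {}
    for k, atom in enumerate(order):
        ang = math.radians(60.0 * k)
        ring[atom] = np.array(
            [radius * math.cos(ang), radius * math.sin(ang), pucker * (-1) ** k]
        )
    normal = np.array([0.0, 0.0, 1.0])
    atoms: dict[str, tuple[str, np.ndarray]] = {a: ("O" if a == "O5" else "C", p)
                                                for a, p in ring.items()}

    def attach(carbon: str, new: str, element: str, bond: float, axial: bool):
        i = order.index(carbon)
        nb1 = ring[order[(i - 1) % 6]]
        nb2 = ring[order[(i + 1) % 6]]
        ax, eq = _substituent_dirs(ring[carbon], nb1, nb2, normal)
        d = ax if axial else eq
        atoms[new] = (element, ring[carbon] + bond * d)

    # beta anomeric oxygen: equatorial in 4C1 for the beta-D series
    attach("C1", "O1", "O", 1.41, axial=False)
    attach("C3", "O3", "O", 1.42, axial=False)
    attach("C4", "O4", "O", 1.42, axial=(name == GALNAC))
    attach("C5", "C6", "C", 1.52, axial=False)
    c6 = atoms["C6"][1]
    out = _unit(c6 - ring["C5"])
    side = _unit(np.cross(out, normal))
    if name == GLCUA:
        attach("C2", "O2", "O", 1.42, axial=False)
        # carboxylate on C6
        atoms["O6A"] = ("O", c6 + 1.25 * _unit(out + 0.9 * side))
        atoms["O6B"] = ("O", c6 + 1.25 * _unit(out - 0.9 * side))
    else:
        attach("C2", "N2", "N", 1.45, axial=False)
        n2 = atoms["N2"][1]
        nd = _unit(n2 - ring["C2"])
        nside = _unit(np.cross(nd, normal))
        c7 = n2 + 1.33 * _unit(nd + 0.4 * nside)
        atoms["C7"] = ("C", c7)
        atoms["O7"] = ("O", c7 + 1.23 * _unit(nside - 0.3 * normal))
        atoms["C8"] = ("C", c7 + 1.50 * _unit(nd + 0.2 * normal))
        atoms["O6"] = ("O", c6 + 1.42 * _unit(out + 0.5 * normal))
    return MonosaccharideTemplate(name, atoms)


TEMPLATES: dict[str, MonosaccharideTemplate] = {
    n: _build_template(n) for n in (GLCUA, GLCNAC, GALNAC)
}


def ring_pucker_signature(coords: np.ndarray) -> np.ndarray:
    """Signed out-of-mean-plane displacements of the six ring atoms.

    A 4C1-like chair alternates in sign around the cycle.
    """
    center = coords.mean(axis=0)
    x = coords - center
    _, _, vt = np.linalg.svd(x)
    normal = vt[2]
    return x @ normal


def is_chair(template: MonosaccharideTemplate, tol: float = 0.05) -> bool:
    """True when the template ring is an alternating chair within ``tol`` A."""
    z = ring_pucker_signature(template.coords(RING_ATOMS))
    if z[0] < 0:
        z = -z
    signs = np.array([1, -1, 1, -1, 1, -1], dtype=float)
    return bool(np.all(z * signs > tol))


# ---------------------------------------------------------------------------
# sequences


def _is_uronic(res: str) -> bool:
    return res == GLCUA


@dataclass(frozen=True)
class GlycanSequence:
    """Ordered residue/linkage description; residue 1 = non-reducing terminus."""

    residues: tuple[str, ...]
    spec: str = ""

    def __post_init__(self):
        if len(self.residues) < 2:
            raise GlycanError("a glycan sequence needs at least 2 residues")
        for i in range(len(self.residues) - 1):
            if _is_uronic(self.residues[i]) == _is_uronic(self.residues[i + 1]):
                raise GlycanError(
                    f"residues {i + 1} and {i + 2} do not alternate uronic/HexNAc"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def linkages(self) -> tuple[str, ...]:
        """Linkage i joins residue i to i+1: 'beta1,3' from GlcUA, else 'beta1,4'."""
        return tuple(
            "beta1,3" if _is_uronic(r) else "beta1,4" for r in self.residues[:-1]
        )

    def ring_class(self, i: int) -> str:
        """'uronic' or 'hexnac' for 1-based ring index ``i``."""
        return "uronic" if _is_uronic(self.residues[i - 1]) else "hexnac"


_HA_RE = re.compile(r"^HA(\d+)\^(AN|NA|AA|NN)$")
_C_RE = re.compile(r"^C(\d+)(?:\^(AN|NA|AA|NN))?$")


def _alternating(n: int, termini: str, hexnac: str) -> tuple[str, ...]:
    if n < 2:
        raise GlycanError(f"oligosaccharide length must be >= 2, got {n}")
    first, last = termini[0], termini[1]
    if n % 2 == 0 and first == last:
        raise GlycanError(
            f"even length {n} cannot have identical termini '{termini}'"
        )
    if n % 2 == 1 and first != last:
        raise GlycanError(
            f"odd length {n} cannot have different termini '{termini}'"
        )
    start = GLCUA if first == "A" else hexnac
    other = hexnac if first == "A" else GLCUA
    res = tuple(start if i % 2 == 0 else other for i in range(n))
    if (res[-1] == GLCUA) != (last == "A"):  # defensive; parity already checks
        raise GlycanError(f"terminal combination '{termini}' impossible for n={n}")
    return res


def parse_sequence(spec: str) -> GlycanSequence:
    """Parse an oligosaccharide specifier into a :class:`GlycanSequence`.

    Supported forms: ``HA{n}^{AN|NA|AA|NN}`` (A = GlcUA, N = GlcNAc at the
    non-reducing and reducing termini respectively), ``C{n}^AN`` (chondroitin;
    ``C{n}`` alone defaults to AN termini), and the hybrid 8-mers ``HA4C4``
    and ``C4HA4``.

    Naming caveat for the hybrids: ``HA4C4`` carries its *chondroitin*
    tetrasaccharide at the non-reducing end (GalNAc at rings 2 and 4) and its
    HA tetrasaccharide at the reducing end; ``C4HA4`` is the reverse. The
    name reads reducing-end-first, not left to right.
    """
    s = spec.strip()
    if s == "HA4C4":
        res = (GLCUA, GALNAC, GLCUA, GALNAC, GLCUA, GLCNAC, GLCUA, GLCNAC)
        return GlycanSequence(res, spec=s)
    if s == "C4HA4":
        res = (GLCUA, GLCNAC, GLCUA, GLCNAC, GLCUA, GALNAC, GLCUA, GALNAC)
        return GlycanSequence(res, spec=s)
    m = _HA_RE.match(s)
    if m:
        n = int(m.group(1))
        return GlycanSequence(_alternating(n, m.group(2), GLCNAC), spec=s)
    m = _C_RE.match(s)
    if m:
        n = int(m.group(1))
        termini = m.group(2) or ("AN" if n % 2 == 0 else "AA")
        return GlycanSequence(_alternating(n, termini, GALNAC), spec=s)
    raise GlycanError(f"unparseable oligosaccharide specifier: {spec!r}")


# ---------------------------------------------------------------------------
# conformers


def _linkage_acceptor_atoms(linkage: str) -> tuple[str, str, str]:
    """(Og name, Cx name, C(x+1) name) on the acceptor residue."""
    if linkage == "beta1,3":
        return "O3", "C3", "C4"
    if linkage == "beta1,4":
        return "O4", "C4", "C5"
    raise GlycanError(f"unknown linkage type {linkage!r}")


@dataclass
class GlycanConformer:
    """Oligosaccharide coordinates; rings are rigid copies of their templates.

    ``residue_atoms[i]`` maps atom name -> row index into ``coords`` for
    0-based residue ``i``. The glycosidic oxygen of linkage i is stored as
    the acceptor's O3/O4; internal anomeric O1 atoms are consumed on linking.
    """

    sequence: GlycanSequence
    coords: np.ndarray
    atom_names: list[str]
    atom_elements: list[str]
    atom_residue: list[int]  # 0-based residue index per atom
    residue_atoms: list[dict[str, int]] = field(repr=False, default_factory=list)

    @property
    def radii(self) -> np.ndarray:
        return np.array([VDW_RADIUS[e] for e in self.atom_elements])

    def atom(self, res_index0: int, name: str) -> np.ndarray:
        try:
            return self.coords[self.residue_atoms[res_index0][name]]
        except KeyError as exc:
            raise GlycanError(
                f"residue {res_index0 + 1} has no atom {name!r}"
            ) from exc

    def ring_coords(self, ring: int) -> np.ndarray:
        """Ring-atom coordinates of 1-based ring index."""
        return np.array([self.atom(ring - 1, a) for a in RING_ATOMS])

    def ring_centroid(self, ring: int) -> np.ndarray:
        return self.ring_coords(ring).mean(axis=0)

    def ring_normal(self, ring: int) -> np.ndarray:
        x = self.ring_coords(ring)
        x = x - x.mean(axis=0)
        _, _, vt = np.linalg.svd(x)
        return vt[2]

    def heavy_indices_of_ring(self, ring: int) -> np.ndarray:
        """All atom rows belonging to 1-based residue ``ring``."""
        return np.flatnonzero(np.asarray(self.atom_residue) == ring - 1)

    def glycosidic_oxygen_indices(self) -> list[int]:
        out = []
        for i, link in enumerate(self.sequence.linkages):
            og, _, _ = _linkage_acceptor_atoms(link)
            out.append(self.residue_atoms[i + 1][og])
        return out

    def glycosidic_bond_lengths(self) -> np.ndarray:
        """|C1(i) - Og(i+1)| per linkage, in Angstrom."""
        vals = []
        for i, link in enumerate(self.sequence.linkages):
            og, _, _ = _linkage_acceptor_atoms(link)
            vals.append(np.linalg.norm(self.atom(i, "C1") - self.atom(i + 1, og)))
        return np.array(vals)

    def transformed(self, r: np.ndarray, t: np.ndarray) -> "GlycanConformer":
        """Rigid-body copy with coords -> R @ x + t."""
        return GlycanConformer(
            sequence=self.sequence,
            coords=self.coords @ r.T + t,
            atom_names=list(self.atom_names),
            atom_elements=list(self.atom_elements),
            atom_residue=list(self.atom_residue),
            residue_atoms=[dict(d) for d in self.residue_atoms],
        )


def build_conformer(sequence: GlycanSequence, torsions) -> GlycanConformer:
    """Place rigid ring templates so each linkage realizes its (Phi, Psi).

    The donor's anomeric oxygen defines the glycosidic oxygen position; the
    acceptor template is rigidly superposed so its O3/O4 coincides with it
    while C3/C4 and the next ring carbon satisfy Phi and Psi exactly.
    """
    torsions = [(float(p), float(q)) for p, q in torsions]
    if len(torsions) != len(sequence) - 1:
        raise GlycanError(
            f"expected {len(sequence) - 1} torsion pairs, got {len(torsions)}"
        )

    placed: list[dict[str, np.ndarray]] = []
    elements: list[dict[str, str]] = []
    t0 = TEMPLATES[sequence.residues[0]]
    placed.append({n: p.copy() for n, (e, p) in t0.atoms.items()})
    elements.append({n: e for n, (e, p) in t0.atoms.items()})

    for i, link in enumerate(sequence.linkages):
        phi, psi = torsions[i]
        donor = placed[i]
        acc_t = TEMPLATES[sequence.residues[i + 1]]
        og_name, cx_name, cn_name = _linkage_acceptor_atoms(link)
        og = donor["O1"]
        r_ogcx = acc_t.bond_length(og_name, cx_name)
        r_cxcn = acc_t.bond_length(cx_name, cn_name)
        ang_ogcxcn = acc_t.bond_angle(og_name, cx_name, cn_name)
        cx = place_atom(donor["O5"], donor["C1"], og, r_ogcx, GLYCOSIDIC_ANGLE, phi)
        cn = place_atom(donor["C1"], og, cx, r_cxcn, ang_ogcxcn, psi)
        moving = acc_t.coords([og_name, cx_name, cn_name])
        rot, tr = kabsch(moving, np.array([og, cx, cn]))
        placed.append({n: rot @ p + tr for n, (e, p) in acc_t.atoms.items()})
        elements.append({n: e for n, (e, p) in acc_t.atoms.items()})
        del donor["O1"]  # consumed by the linkage; acceptor Og is the bond oxygen
        del elements[i]["O1"]

    coords, names, elems, residx = [], [], [], []
    residue_atoms: list[dict[str, int]] = []
    for i, resat in enumerate(placed):
        table: dict[str, int] = {}
        for n, p in resat.items():
            table[n] = len(coords)
            coords.append(p)
            names.append(n)
            elems.append(elements[i][n])
            residx.append(i)
        residue_atoms.append(table)
    return GlycanConformer(
        sequence=sequence,
        coords=np.array(coords),
        atom_names=names,
        atom_elements=elems,
        atom_residue=residx,
        residue_atoms=residue_atoms,
    )


def measure_torsions(conformer: GlycanConformer) -> list[tuple[float, float]]:
    """Per-linkage (Phi, Psi) in degrees under :data:`DIHEDRAL_CONVENTION`."""
    out = []
    for i, link in enumerate(conformer.sequence.linkages):
        og_name, cx_name, cn_name = _linkage_acceptor_atoms(link)
        try:
            o5 = conformer.atom(i, "O5")
            c1 = conformer.atom(i, "C1")
            og = conformer.atom(i + 1, og_name)
            cx = conformer.atom(i + 1, cx_name)
            cn = conformer.atom(i + 1, cn_name)
        except GlycanError as exc:
            raise GlycanError(f"linkage {i + 1} ({link}): {exc}") from exc
        out.append((dihedral(o5, c1, og, cx), dihedral(c1, og, cx, cn)))
    return out


# ---------------------------------------------------------------------------
# PDB I/O


def conformer_to_pdb(conformer: GlycanConformer, path, chain: str = "X") -> None:
    """Write the conformer as a single-model PDB (BDP/NAG/A2G residues)."""
    st = gemmi.Structure()
    st.name = conformer.sequence.spec or "glycan"
    model = gemmi.Model("1")
    ch = gemmi.Chain(chain)
    for i, resname in enumerate(conformer.sequence.residues):
        res = gemmi.Residue()
        res.name = PDB_RESNAME[resname]
        res.seqid = gemmi.SeqId(i + 1, " ")
        for name, idx in conformer.residue_atoms[i].items():
            at = gemmi.Atom()
            at.name = name
            at.element = gemmi.Element(conformer.atom_elements[idx])
            x, y, z = conformer.coords[idx]
            at.pos = gemmi.Position(x, y, z)
            res.add_atom(at)
        ch.add_residue(res)
    model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def conformer_from_pdb(path, chain: str = "X") -> GlycanConformer:
    """Read a conformer previously written by :func:`conformer_to_pdb`."""
    st = gemmi.read_structure(str(path))
    model = st[0]
    residues = []
    coords, names, elems, residx = [], [], [], []
    residue_atoms: list[dict[str, int]] = []
    found = None
    for ch in model:
        if ch.name == chain:
            found = ch
            break
    if found is None:
        raise GlycanError(f"no chain {chain!r} in {path}")
    for i, res in enumerate(found):
        if res.name not in PDB_RESNAME_INV:
            raise GlycanError(f"unknown sugar residue {res.name!r}")
        residues.append(PDB_RESNAME_INV[res.name])
        table: dict[str, int] = {}
        for at in res:
            table[at.name] = len(coords)
            coords.append([at.pos.x, at.pos.y, at.pos.z])
            names.append(at.name)
            elems.append(at.element.name)
            residx.append(i)
        residue_atoms.append(table)
    return GlycanConformer(
        sequence=GlycanSequence(tuple(residues)),
        coords=np.array(coords),
        atom_names=names,
        atom_elements=elems,
        atom_residue=residx,
        residue_atoms=residue_atoms,
    )
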