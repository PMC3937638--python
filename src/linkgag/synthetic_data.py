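"""Seed-deterministic synthetic fixtures for every pipeline stage.

The receptor fixture is an explicitly non-physical test scaffold: a sparse
pseudo-protein carrying only the groove anchor side chains (His45 imidazole,
Lys11/Lys63/Arg81 terminal amines/guanidinium, Tyr12/Tyr59/Tyr78, Ile61,
the Cys47-Cys68 sulfur pair) arranged around a reference HA octasaccharide
conformer so that the bundled restraints are satisfied with zero penalty,
no steric clashes, and seven of the eight rings in protein contact. A real
receptor PDB (e.g. an NMR ensemble of the Link module) can be substituted
anywhere a fixture receptor is used.

CSP panels are synthesized by inverting the register-inference logic: each
reporter's complex peak is placed at a class-specific canonical position
(plus optional jitter), so zero-noise panels round-trip exactly. ITC series
are simulated from the reported one-site parameters under the published
injection protocol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .complex_modeler import Receptor
from .csp_register import (
    CLASS_SHIFTS,
    REPORTER_FREE_PEAKS,
    REPORTER_LABELS,
    GrooveModel,
    PeakList,
    Register,
    ReporterRuleTable,
    predict_classes,
)
from .glycan_builder import (
    GlycanConformer,
    GlycanSequence,
    build_conformer,
    parse_sequence,
)
from .itc_thermo import (
    BindingParams,
    ITCProtocol,
    ITCSeries,
    load_reported_panel,
    model_heats,
    simulate_blank,
    simulate_titration,
)
from .torsion_maps import TorsionMap, DEFAULT_SPACING


@dataclass
class FixtureSpec:
    """Geometry and noise knobs for fixture generation (seed-deterministic)."""

    seed: int = 0
    stack_distance: float = 3.5
    methyl_distance: float = 3.9
    contact_distance: float = 3.6
    salt_distance: float = 3.0
    peak_noise_ppm: tuple[float, float] = (0.0, 0.0)  # (15N, 1H)
    itc_noise_ucal: float = 0.0


# ---------------------------------------------------------------------------
# torsion-map fixtures


def basin_energy(basins, phi: float, psi: float, baseline: float = 8.0) -> float:
    """Closed-form smooth multi-basin surface (periodic Gaussian wells)."""
    e = baseline
    for phi0, psi0, depth, width in basins:
        dphi = (phi - phi0 + 180.0) % 360.0 - 180.0
        dpsi = (psi - psi0 + 180.0) % 360.0 - 180.0
        e -= depth * math.exp(-(dphi ** 2 + dpsi ** 2) / (2.0 * width ** 2))
    return e


def make_torsion_map_fixture(basins, linkage: str = "beta1,3",
                             spacing: float = DEFAULT_SPACING,
                             baseline: float = 8.0) -> TorsionMap:
    """Grid a smooth basin surface; the map normalizes its minimum to zero."""
    if not basins:
        raise ValueError("at least one basin is required")
    n = int(round(360.0 / spacing))
    axis = -180.0 + spacing * np.arange(n)
    grid = np.array(
        [[basin_energy(basins, p, q, baseline) for q in axis] for p in axis]
    )
    return TorsionMap(linkage=linkage, grid=grid, spacing=spacing)


#: default basin layouts per linkage type (centers on 10-degree grid nodes)
FIXTURE_BASINS = {
    "beta1,3": [(-80.0, -120.0, 6.0, 30.0), (60.0, -100.0, 3.0, 25.0)],
    "beta1,4": [(-80.0, -110.0, 6.0, 30.0), (50.0, -100.0, 3.0, 25.0)],
}


def fixture_maps() -> dict[str, TorsionMap]:
    return {
        link: make_torsion_map_fixture(basins, linkage=link)
        for link, basins in FIXTURE_BASINS.items()
    }


def reference_torsions(sequence: GlycanSequence) -> list[tuple[float, float]]:
    """Per-linkage global-minimum torsions of the fixture maps."""
    return [FIXTURE_BASINS[l][0][:2] for l in sequence.linkages]


# ---------------------------------------------------------------------------
# receptor fixture


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _fibonacci_sphere(n: int = 400) -> np.ndarray:
    k = np.arange(n)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def _clear_direction(anchor: np.ndarray, ligand_coords: np.ndarray,
                     anchor_index: int, reach: float) -> np.ndarray:
    """Unit direction from ``anchor`` whose swept segment (out to ``reach``)
    stays as far as possible from every other ligand atom."""
    others = np.delete(ligand_coords, anchor_index, axis=0)
    best_u, best_d = None, -1.0
    for u in _fibonacci_sphere():
        probes = anchor[None, :] + np.outer(np.linspace(1.0, reach, 4), u)
        d = np.min(np.linalg.norm(others[None, :, :] - probes[:, None, :], axis=-1))
        if d > best_d:
            best_d, best_u = d, u
    return best_u


def _ring_frame(conf: GlycanConformer, ring: int, away_from: np.ndarray):
    c = conf.ring_centroid(ring)
    n = conf.ring_normal(ring)
    if np.dot(n, c - away_from) < 0:
        n = -n
    return c, n


def _polygon(center: np.ndarray, normal: np.ndarray, n_atoms: int,
             radius: float) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, normal)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(normal, ref))
    v = np.cross(normal, u)
    pts = []
    for k in range(n_atoms):
        a = 2.0 * math.pi * k / n_atoms
        pts.append(center + radius * (math.cos(a) * u + math.sin(a) * v))
    return np.array(pts)


def make_receptor_fixture(spec: Optional[FixtureSpec] = None
                          ) -> tuple[Receptor, GlycanConformer]:
    """Pseudo-receptor built around a reference HA8^AN pose.

    Returns (receptor, reference ligand conformer). By construction the
    bundled default restraints evaluate to zero on the reference pose, the
    pose is clash-free, and rings 1-7 (but not 8) contact the receptor
    within 4.0 A.
    """
    spec = spec or FixtureSpec()
    seq = parse_sequence("HA8^AN")
    lig = build_conformer(seq, reference_torsions(seq))
    center = lig.coords.mean(axis=0)

    names: list[str] = []
    resnames: list[str] = []
    resnums: list[int] = []
    elements: list[str] = []
    coords: list[np.ndarray] = []

    def add(resname: str, resnum: int, atom_specs):
        for name, el, xyz in atom_specs:
            names.append(name)
            resnames.append(resname)
            resnums.append(resnum)
            elements.append(el)
            coords.append(np.asarray(xyz, dtype=float))

    # His45 imidazole stacked on ring 1 at the target distance, parallel planes
    c1, n1 = _ring_frame(lig, 1, center)
    his_center = c1 + spec.stack_distance * n1
    his_ring = _polygon(his_center, n1, 5, 1.16)
    add("HIS", 45, [
        ("CG", "C", his_ring[0]),
        ("ND1", "N", his_ring[1]),
        ("CE1", "C", his_ring[2]),
        ("NE2", "N", his_ring[3]),
        ("CD2", "C", his_ring[4]),
    ])
    add("HIS", 45, [("CB", "C", his_center + 2.6 * n1)])

    # Lys63 ammonium against the ring-1 carboxylate
    o6a_1 = lig.atom(0, "O6A")
    u = _clear_direction(o6a_1, lig.coords,
                         lig.residue_atoms[0]["O6A"], spec.salt_distance + 1.5)
    add("LYS", 63, [("NZ", "N", o6a_1 + spec.salt_distance * u),
                    ("CE", "C", o6a_1 + (spec.salt_distance + 1.5) * u)])

    # Cys47/Cys68 disulfide sulfurs under rings 2 and 3
    c2, n2 = _ring_frame(lig, 2, center)
    c3, n3 = _ring_frame(lig, 3, center)
    sg47 = c2 + spec.contact_distance * n2
    sg68 = c3 + spec.contact_distance * n3
    add("CYS", 47, [("SG", "S", sg47), ("CB", "C", sg47 + 1.8 * n2)])
    add("CYS", 68, [("SG", "S", sg68), ("CB", "C", sg68 + 1.8 * n3)])

    # Lys11 ammonium against the ring-3 carboxylate
    o6a_3 = lig.atom(2, "O6A")
    u = _clear_direction(o6a_3, lig.coords,
                         lig.residue_atoms[2]["O6A"], spec.salt_distance + 1.5)
    add("LYS", 11, [("NZ", "N", o6a_3 + spec.salt_distance * u),
                    ("CE", "C", o6a_3 + (spec.salt_distance + 1.5) * u)])

    # Ile61 terminal carbon forming the methyl pocket at ring 4
    c8_4 = lig.atom(3, "C8")
    u = _clear_direction(c8_4, lig.coords,
                         lig.residue_atoms[3]["C8"], spec.methyl_distance + 3.0)
    add("ILE", 61, [("CD1", "C", c8_4 + spec.methyl_distance * u),
                    ("CG1", "C", c8_4 + (spec.methyl_distance + 1.5) * u),
                    ("CB", "C", c8_4 + (spec.methyl_distance + 3.0) * u)])

    # Tyr12 hydroxyl hydrogen-bonding the ring-4 O4 (the HexNAc C4-OH)
    o4_4 = lig.atom(3, "O4")
    u = _clear_direction(o4_4, lig.coords,
                         lig.residue_atoms[3]["O4"], spec.salt_distance + 1.4)
    add("TYR", 12, [("OH", "O", o4_4 + spec.salt_distance * u),
                    ("CZ", "C", o4_4 + (spec.salt_distance + 1.4) * u)])

    # Tyr59 / Tyr78 rings stacked under rings 5 and 6
    for resnum, ring in ((59, 5), (78, 6)):
        c, n = _ring_frame(lig, ring, center)
        ring_center = c + 3.8 * n
        hexagon = _polygon(ring_center, n, 6, 1.39)
        add("TYR", resnum, [
            ("CG", "C", hexagon[0]),
            ("CD1", "C", hexagon[1]),
            ("CE1", "C", hexagon[2]),
            ("CZ", "C", hexagon[3]),
            ("CE2", "C", hexagon[4]),
            ("CD2", "C", hexagon[5]),
        ])
        add("TYR", resnum, [("OH", "O", ring_center + 2.8 * n)])

    # Arg81 guanidinium against the ring-7 carboxylate
    o6a_7 = lig.atom(6, "O6A")
    u = _clear_direction(o6a_7, lig.coords,
                         lig.residue_atoms[6]["O6A"], spec.salt_distance + 2.7)
    nh1 = o6a_7 + spec.salt_distance * u
    cz = nh1 + 1.35 * u
    add("ARG", 81, [("NH1", "N", nh1), ("CZ", "C", cz),
                    ("NH2", "N", cz + 1.35 * u)])

    receptor = Receptor(names, resnames, resnums, np.array(coords), elements)
    return receptor, lig


def write_receptor_fixture(path, spec: Optional[FixtureSpec] = None,
                           n_models: int = 20) -> None:
    """Write the fixture receptor as a multi-model PDB (identical members,
    mirroring an NMR-ensemble file layout)."""
    import gemmi

    receptor, _ = make_receptor_fixture(spec)
    st = gemmi.Structure()
    st.name = "synthetic-link-module-fixture"
    for mi in range(1, n_models + 1):
        model = gemmi.Model(str(mi))
        ch = gemmi.Chain("A")
        res_map: dict[int, gemmi.Residue] = {}
        for name, rname, rnum, xyz, el in zip(
            receptor.atom_names, receptor.res_names, receptor.res_nums,
            receptor.coords, receptor.elements,
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
        model.add_chain(ch)
        st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# CSP panels


#: true binding registers (offsets) for the ten-oligomer panel; dual entries
#: are species bound in two registers simultaneously
DEFAULT_TRUTH_REGISTERS: dict[str, tuple[int, ...]] = {
    "HA8^AN": (0,),
    "HA8^NA": (-1, 1),
    "HA7^AA": (0,),
    "HA7^NN": (-1, 1),
    "HA6^AN": (0,),
    "HA6^NA": (1,),
    "HA5^AA": (2,),
    "HA5^NN": (1,),
    "HA4^AN": (2,),
    "HA4^NA": (1,),
}

#: filler (non-reporter) amides included in every synthetic peak list
_FILLER_PEAKS = {"G10N-H": (109.40, 8.10), "T73N-H": (112.80, 8.60)}


def make_csp_panel(truth: Optional[dict[str, tuple[int, ...]]] = None,
                   rules: Optional[ReporterRuleTable] = None,
                   groove: Optional[GrooveModel] = None,
                   noise_ppm: tuple[float, float] = (0.0, 0.0),
                   seed: int = 0):
    """Synthesize free/complex peak-list pairs for a panel of oligomers.

    Returns ``(panel, truth_registers)`` where panel maps oligomer spec ->
    (reference PeakList, complex PeakList) and truth_registers maps spec ->
    list of Register. Each reporter's complex peak sits at its class
    canonical position (one peak per distinct class across the truth
    registers, so dual-register species emit two peaks); reporters whose
    class is unclassified keep their free-peak position. Gaussian jitter
    (15N, 1H) ppm is applied with the given seed.
    """
    truth = truth or DEFAULT_TRUTH_REGISTERS
    rules = rules or ReporterRuleTable()
    groove = groove or GrooveModel()
    rng = np.random.default_rng(seed)
    panel: dict[str, tuple[PeakList, PeakList]] = {}
    registers: dict[str, list[Register]] = {}
    for spec_name, offsets in truth.items():
        seq = parse_sequence(spec_name)
        regs = [Register(seq, off, groove) for off in offsets]
        registers[spec_name] = regs
        ref_entries = dict(_FILLER_PEAKS)
        cpx_entries = dict(_FILLER_PEAKS)
        for rep in rules.reporters():
            root = REPORTER_LABELS[rep]
            free = REPORTER_FREE_PEAKS[rep]
            ref_entries[root] = free
            labels = []
            for reg in regs:
                cls = predict_classes(reg, rules)[rep]
                if cls not in labels:
                    labels.append(cls)
            for k, cls in enumerate(labels):
                key = root if k == 0 else f"{root}{chr(ord('b') + k - 1)}"
                if cls is None:
                    pos = free
                else:
                    dn, dh = CLASS_SHIFTS[rep][cls]
                    pos = (free[0] + dn, free[1] + dh)
                jitter = (
                    rng.normal(0.0, noise_ppm[0]) if noise_ppm[0] > 0 else 0.0,
                    rng.normal(0.0, noise_ppm[1]) if noise_ppm[1] > 0 else 0.0,
                )
                cpx_entries[key] = (pos[0] + jitter[0], pos[1] + jitter[1])
        panel[spec_name] = (
            PeakList(dict(ref_entries), nuclei="15N"),
            PeakList(dict(cpx_entries), nuclei="15N"),
        )
    return panel, registers


# ---------------------------------------------------------------------------
# ITC datasets


def reported_binding_params(name: str) -> BindingParams:
    """One-site parameters for a panel member from the bundled table."""
    df = load_reported_panel()
    row = df[df["name"] == name]
    if row.empty:
        raise KeyError(f"no reported parameters for {name!r}")
    r = row.iloc[0]
    dh = float(r["dH"]) if np.isfinite(r["dH"]) else -7.0
    return BindingParams(n=float(r["N"]), kb=float(r["Kb_1e5"]) * 1e5, dh=dh)


def make_itc_dataset(names: Optional[list[str]] = None,
                     protocol: Optional[ITCProtocol] = None,
                     noise_fraction: float = 0.0,
                     seed: int = 0):
    """Simulated titration series (plus a blank) for panel members.

    ``noise_fraction`` scales Gaussian heat noise to the largest noiseless
    injection heat of each series. Returns (series dict, blank, truth dict).
    """
    protocol = protocol or ITCProtocol()
    df = load_reported_panel()
    if names is None:
        names = [n for n in df["name"] if np.isfinite(
            df.set_index("name").loc[n, "dH"])]
    rng = np.random.default_rng(seed)
    series: dict[str, ITCSeries] = {}
    truth: dict[str, BindingParams] = {}
    for name in names:
        params = reported_binding_params(name)
        truth[name] = params
        q0 = model_heats(params.n, params.kb, params.dh, protocol)
        sd = noise_fraction * float(np.max(np.abs(q0)))
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        series[name] = simulate_titration(params, protocol,
                                          noise_sd_ucal=sd, seed=sub_seed)
    blank = simulate_blank(protocol)
    return series, blank, truth
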