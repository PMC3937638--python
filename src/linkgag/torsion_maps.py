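"""Periodic Phi/Psi energy surfaces for glycosidic linkages.

Each linkage type (beta1,3 or beta1,4) carries a regular energy grid over
[-180, 180)^2 in kcal/mol, normalized so the global minimum is zero. Models
are screened by interpolating every linkage's measured torsions on the map
for its type: a linkage is *favored* when its energy lies within a cutoff of
the minimum (default 4 kcal/mol, i.e. two contour intervals of a 2 kcal/mol
contour spacing), and a model is accepted only when every linkage is favored.

The molecular-dynamics maps the screening emulates are not distributed with
the package; the bundled defaults are smooth two-basin surrogates (see
:mod:`linkgag.synthetic_data`) and user grids are read from a small text
format with a three-line header.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .glycan_builder import DIHEDRAL_CONVENTION, GlycanConformer, measure_torsions

DEFAULT_CUTOFF = 4.0  # kcal/mol above the map minimum
DEFAULT_SPACING = 10.0  # degrees


class MapError(ValueError):
    pass


@dataclass
class TorsionMap:
    """Periodic (Phi, Psi) energy grid for one linkage type.

    ``grid[i, j]`` is the energy at Phi = -180 + i * spacing,
    Psi = -180 + j * spacing; both axes wrap with period 360.
    """

    linkage: str
    grid: np.ndarray
    spacing: float = DEFAULT_SPACING
    convention: str = DIHEDRAL_CONVENTION

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise MapError("grid must be 2-D")
        if not np.all(np.isfinite(self.grid)):
            raise MapError("grid energies must be finite")
        n_phi = int(round(360.0 / self.spacing))
        if self.grid.shape[0] != n_phi or self.grid.shape[1] != n_phi:
            raise MapError(
                f"grid shape {self.grid.shape} inconsistent with spacing "
                f"{self.spacing} deg over [-180, 180)"
            )
        self.grid = self.grid - self.grid.min()

    def minimum_location(self) -> tuple[float, float]:
        i, j = np.unravel_index(int(np.argmin(self.grid)), self.grid.shape)
        return (-180.0 + i * self.spacing, -180.0 + j * self.spacing)


def map_energy(tmap: TorsionMap, phi: float, psi: float) -> float:
    """Bilinear interpolation on the periodic grid, kcal/mol."""
    n = tmap.grid.shape[0]
    fi = (float(phi) + 180.0) / tmap.spacing
    fj = (float(psi) + 180.0) / tmap.spacing
    i0 = int(np.floor(fi))
    j0 = int(np.floor(fj))
    di = fi - i0
    dj = fj - j0
    g = tmap.grid
    i0 %= n
    j0 %= n
    i1 = (i0 + 1) % n
    j1 = (j0 + 1) % n
    return float(
        g[i0, j0] * (1 - di) * (1 - dj)
        + g[i1, j0] * di * (1 - dj)
        + g[i0, j1] * (1 - di) * dj
        + g[i1, j1] * di * dj
    )


def nearest_node_energy(tmap: TorsionMap, phi: float, psi: float) -> float:
    """Energy at the grid node nearest to (phi, psi); used as a cross-check."""
    n = tmap.grid.shape[0]
    i = int(np.round((float(phi) + 180.0) / tmap.spacing)) % n
    j = int(np.round((float(psi) + 180.0) / tmap.spacing)) % n
    return float(tmap.grid[i, j])


@dataclass
class FavoredVerdict:
    """Per-linkage energies/flags and the conjunction accept flag."""

    energies: list[float]
    favored: list[bool]

    @property
    def accept(self) -> bool:
        return all(self.favored)


def classify_linkages(
    conformer: GlycanConformer,
    maps: dict[str, TorsionMap],
    cutoff: float = DEFAULT_CUTOFF,
) -> FavoredVerdict:
    """Score every linkage of ``conformer`` on the map for its type.

    Raises :class:`MapError` if a map is missing for a linkage type or was
    produced under a different dihedral convention (mixing conventions would
    silently score the wrong surface).
    """
    torsions = measure_torsions(conformer)
    energies: list[float] = []
    favored: list[bool] = []
    for link, (phi, psi) in zip(conformer.sequence.linkages, torsions):
        if link not in maps:
            raise MapError(f"no torsion map for linkage type {link!r}")
        tmap = maps[link]
        if tmap.convention != DIHEDRAL_CONVENTION:
            raise MapError(
                f"map convention {tmap.convention!r} does not match the "
                f"builder convention {DIHEDRAL_CONVENTION!r}"
            )
        e = map_energy(tmap, phi, psi)
        energies.append(e)
        favored.append(e <= cutoff)
    return FavoredVerdict(energies=energies, favored=favored)


# ---------------------------------------------------------------------------
# file format: 3-line header (# linkage, # spacing_deg, # convention) + matrix


def save_map(tmap: TorsionMap, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# linkage: {tmap.linkage}\n")
        fh.write(f"# spacing_deg: {tmap.spacing:g}\n")
        fh.write(f"# convention: {tmap.convention}\n")
        np.savetxt(fh, tmap.grid, fmt="%.6f")


def load_map(path) -> TorsionMap:
    """Read a grid file; the map is normalized so its minimum is zero."""
    header: dict[str, str] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                header[key.strip()] = value.strip()
                continue
            rows.append([float(tok) for tok in line.split()])
    if not rows:
        raise MapError(f"no grid data in {path}")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise MapError(f"non-rectangular grid in {path}")
    for key in ("linkage", "spacing_deg", "convention"):
        if key not in header:
            raise MapError(f"missing header line '# {key}:' in {path}")
    convention = header["convention"]
    if convention != DIHEDRAL_CONVENTION:
        raise MapError(
            f"unknown dihedral convention tag {convention!r} in {path}"
        )
    return TorsionMap(
        linkage=header["linkage"],
        grid=np.array(rows),
        spacing=float(header["spacing_deg"]),
        convention=convention,
    )


def default_maps() -> dict[str, TorsionMap]:
    """Bundled surrogate maps (one per linkage type), minima normalized to 0.

    These are smooth approximations standing in for published MD surfaces;
    screening decisions against experimental data should use user-supplied
    grids via :func:`load_map`.
    """
    data = Path(__file__).parent / "data"
    return {
        "beta1,3": load_map(data / "beta13_default.map"),
        "beta1,4": load_map(data / "beta14_default.map"),
    }
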