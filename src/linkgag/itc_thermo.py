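"""One-site isothermal titration calorimetry: simulation, fitting, tables.

The single-site model treats the cell protein as carrying N equivalent
independent sites with association constant Kb (M^-1) and molar binding
enthalpy dH (kcal/mol). Injection bookkeeping uses a growing active volume:
cell solutes are conserved (nothing is ejected) and every injection dilutes
the cell contents while adding syringe ligand, so the cumulative heat of a
saturating titration equals N * dH * (protein moles loaded in the cell).

Per-injection heat i is the change in total complex content,

    q_i = dH * (B_i V_i - B_{i-1} V_{i-1})        [kcal -> microcal]

with B the equilibrium complex concentration from the stable root of the
mass-action quadratic. Fitting is nonlinear least squares over (N, Kb, dH)
with Kb handled on a log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import lmfit
import numpy as np

R_KCAL = 1.9872e-3  # gas constant, kcal mol^-1 K^-1
DEFAULT_TEMPERATURE = 298.15  # K, the 25 C experiment temperature
DEFAULT_CELL_VOLUME_ML = 1.4  # VP-ITC nominal cell volume
KCAL_TO_UCAL = 1e9


class ITCError(ValueError):
    pass


@dataclass
class ITCProtocol:
    """Instrument protocol: volumes in ml/ul, concentrations in mM."""

    cell_volume_ml: float = DEFAULT_CELL_VOLUME_ML
    injection_volumes_ul: tuple[float, ...] = tuple([5.0] * 26)
    cell_conc_mM: float = 0.015
    syringe_conc_mM: float = 0.24
    temperature_K: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        if self.cell_volume_ml <= 0 or self.cell_conc_mM <= 0 \
                or self.syringe_conc_mM <= 0 or self.temperature_K <= 0:
            raise ITCError("protocol volumes, concentrations and temperature must be positive")
        if any(v <= 0 for v in self.injection_volumes_ul):
            raise ITCError("injection volumes must be positive")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes_ul)


@dataclass
class ITCSeries:
    """Per-injection heats in microcal (blank-corrected unless noted)."""

    heats_ucal: np.ndarray
    protocol: Optional[ITCProtocol] = None

    def __post_init__(self):
        self.heats_ucal = np.asarray(self.heats_ucal, dtype=float)
        if self.protocol is not None and len(self.heats_ucal) != self.protocol.n_injections:
            raise ITCError(
                f"series length {len(self.heats_ucal)} does not match protocol "
                f"({self.protocol.n_injections} injections)"
            )


@dataclass
class BindingParams:
    """One-site parameters: stoichiometry N, Kb (M^-1), dH (kcal/mol)."""

    n: float
    kb: float
    dh: float
    n_err: float = float("nan")
    kb_err: float = float("nan")
    dh_err: float = float("nan")
    converged: bool = True
    message: str = ""

    def __post_init__(self):
        if self.kb <= 0:
            raise ITCError("Kb must be positive")


@dataclass
class ThermoRow:
    """Derived thermodynamics; TdS = dH - dG is an arithmetic identity."""

    dg: float
    dh: float
    tds: float
    kd: float
    percent_of_reference: Optional[float] = None


def _bound_concentration(n: float, kb: float, mt: np.ndarray, xt: np.ndarray) -> np.ndarray:
    """Equilibrium complex concentration, numerically stable for any c.

    Solves B^2 - B (Xt + N Mt + 1/Kb) + N Mt Xt = 0 via the subtraction-free
    root, which stays accurate when Kb is extremely large (saturation).
    """
    kd = 1.0 / kb
    s = xt + n * mt + kd
    disc = np.sqrt(np.maximum(s * s - 4.0 * n * mt * xt, 0.0))
    return 2.0 * n * mt * xt / (s + disc)


def titration_concentrations(protocol: ITCProtocol) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(cell protein M, total ligand M, active volume L) after each injection."""
    v0 = protocol.cell_volume_ml * 1e-3
    inj = np.asarray(protocol.injection_volumes_ul, dtype=float) * 1e-6
    vol = v0 + np.cumsum(inj)
    n_protein = protocol.cell_conc_mM * 1e-3 * v0
    n_ligand = protocol.syringe_conc_mM * 1e-3 * np.cumsum(inj)
    return n_protein / vol, n_ligand / vol, vol


def model_heats(n: float, kb: float, dh: float, protocol: ITCProtocol) -> np.ndarray:
    """Noiseless per-injection heats in microcal for the one-site model."""
    mt, xt, vol = titration_concentrations(protocol)
    bound = _bound_concentration(n, kb, mt, xt)
    content = bound * vol  # mol of complex
    prev = np.concatenate([[0.0], content[:-1]])
    return dh * (content - prev) * KCAL_TO_UCAL


def simulate_titration(params: BindingParams, protocol: ITCProtocol,
                       noise_sd_ucal: float = 0.0,
                       seed: Optional[int] = None) -> ITCSeries:
    """Simulate a titration; Gaussian heat noise is seeded and reproducible."""
    q = model_heats(params.n, params.kb, params.dh, protocol)
    if noise_sd_ucal > 0:
        rng = np.random.default_rng(seed)
        q = q + rng.normal(0.0, noise_sd_ucal, size=q.shape)
    return ITCSeries(heats_ucal=q, protocol=protocol)


def simulate_blank(protocol: ITCProtocol,
                   dilution_heat_ucal: float = -0.8,
                   noise_sd_ucal: float = 0.0,
                   seed: Optional[int] = None) -> ITCSeries:
    """Heats of injecting ligand into buffer alone (constant dilution heat)."""
    q = np.full(protocol.n_injections, dilution_heat_ucal)
    if noise_sd_ucal > 0:
        rng = np.random.default_rng(seed)
        q = q + rng.normal(0.0, noise_sd_ucal, size=q.shape)
    return ITCSeries(heats_ucal=q, protocol=protocol)


def fit_one_site(series: ITCSeries, protocol: ITCProtocol,
                 blank: Optional[ITCSeries] = None,
                 discard_first: bool = False) -> BindingParams:
    """Nonlinear least-squares fit of (N, Kb, dH) to an injection-heat series.

    The blank (ligand-into-buffer) series, when provided, is subtracted
    point-wise first. Starting values: N = 1, dH from the total evolved heat
    against the cell protein content, and Kb scanned over a log grid for the
    best initial residual. Non-convergence is flagged on the returned
    parameters (``converged=False``), never raised silently.
    """
    q = np.asarray(series.heats_ucal, dtype=float)
    if blank is not None:
        q = q - np.asarray(blank.heats_ucal, dtype=float)
    mask = np.ones(len(q), dtype=bool)
    if discard_first:
        mask[0] = False
    if mask.sum() < 5:
        raise ITCError("need at least 5 usable injections to fit three parameters")

    v0 = protocol.cell_volume_ml * 1e-3
    n_protein = protocol.cell_conc_mM * 1e-3 * v0
    dh0 = float(np.sum(q)) / KCAL_TO_UCAL / n_protein
    if abs(dh0) < 1e-3:
        dh0 = -1.0

    def residual(p):
        model = model_heats(p["n"].value, 10.0 ** p["log10_kb"].value,
                            p["dh"].value, protocol)
        return (model - q)[mask]

    best = None
    for log_kb0 in (3.0, 4.5, 6.0, 7.5, 9.0):
        params = lmfit.Parameters()
        params.add("n", value=1.0, min=0.05, max=10.0)
        params.add("log10_kb", value=log_kb0, min=0.0, max=12.0)
        params.add("dh", value=dh0, min=-100.0, max=100.0)
        try:
            res = lmfit.minimize(residual, params, method="leastsq")
        except Exception:  # pragma: no cover - lmfit internal failure
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise ITCError("one-site fit failed to evaluate")

    p = best.params
    kb = 10.0 ** p["log10_kb"].value
    kb_err = float("nan")
    if p["log10_kb"].stderr is not None:
        kb_err = kb * math.log(10.0) * p["log10_kb"].stderr
    resid = residual(p)
    signal = np.max(np.abs(q[mask])) if np.any(mask) else 0.0
    converged = bool(best.success) and bool(signal > 0) and \
        bool(math.sqrt(np.mean(resid ** 2)) < 0.5 * signal)
    return BindingParams(
        n=float(p["n"].value),
        kb=float(kb),
        dh=float(p["dh"].value),
        n_err=p["n"].stderr if p["n"].stderr is not None else float("nan"),
        kb_err=kb_err,
        dh_err=p["dh"].stderr if p["dh"].stderr is not None else float("nan"),
        converged=converged,
        message="" if converged else "fit flagged: poor convergence or no signal",
    )


# ---------------------------------------------------------------------------
# derived thermodynamics


def derive_thermo(params: BindingParams,
                  temperature: float = DEFAULT_TEMPERATURE,
                  reference_kb: Optional[float] = None) -> ThermoRow:
    """dG = -RT ln Kb; TdS = dH - dG; percent = 100 Kb / Kb(reference)."""
    if params.kb <= 0 or (reference_kb is not None and reference_kb <= 0):
        raise ITCError("association constants must be positive")
    dg = -R_KCAL * temperature * math.log(params.kb)
    tds = params.dh - dg
    percent = 100.0 * params.kb / reference_kb if reference_kb else None
    return ThermoRow(dg=dg, dh=params.dh, tds=tds, kd=1.0 / params.kb,
                     percent_of_reference=percent)


def printed_percent(percent: float) -> float:
    """Relative-affinity column at printed precision: one decimal below 100,
    whole numbers at or above 100."""
    if percent >= 100.0:
        return float(round(percent))
    return round(percent, 1)


def build_affinity_table(panel: list[tuple[str, BindingParams]],
                         reference_name: str,
                         temperature: float = DEFAULT_TEMPERATURE):
    """Thermodynamic table (one row per oligomer) with the percent column
    relative to ``reference_name`` at printed precision."""
    import pandas as pd

    names = [name for name, _ in panel]
    if reference_name not in names:
        raise ITCError(f"reference {reference_name!r} not present in panel")
    ref_kb = dict(panel)[reference_name].kb
    rows = []
    for name, params in panel:
        t = derive_thermo(params, temperature=temperature, reference_kb=ref_kb)
        rows.append(
            {
                "oligosaccharide": name,
                "N": params.n,
                "Kb_1e5_per_M": params.kb / 1e5,
                "dG_kcal_mol": t.dg,
                "dH_kcal_mol": t.dh,
                "TdS_kcal_mol": t.tds,
                "percent_of_reference": printed_percent(t.percent_of_reference),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reported binding parameters shipped with the package


@dataclass(frozen=True)
class PanelEntry:
    name: str
    n: float
    kb_1e5: float
    dg: Optional[float]
    dh: Optional[float]
    tds: Optional[float]
    percent_printed: float


def load_reported_panel():
    """The reported one-site parameters and derived columns for the 13
    oligosaccharides, as a pandas DataFrame (missing entries are NaN)."""
    import pandas as pd
    from pathlib import Path

    path = Path(__file__).parent / "data" / "binding_panel.csv"
    return pd.read_csv(path)
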