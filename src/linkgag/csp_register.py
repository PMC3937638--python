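"""Chemical-shift-perturbation analysis and binding-register inference.

The Link-module groove is modeled as eight numbered positions (odd positions
hold uronic acids) with a fixed per-position interaction feature table
(His45 stack + Lys63 salt bridge at 1, the Cys47/Cys68 disulfide contact at
2, the Lys11 salt bridge at 3, the Ile61 methyl pocket + Tyr12 H-bond at 4,
the Tyr59 and Tyr78 stacks at 5 and 6, the Arg81 salt bridge at 7, nothing
at 8). A *register* places an oligomer so ring r sits at groove position
``offset + r``; up to two rings may overhang each end and at least four
rings must lie in the groove.

Reporter residues respond to occupancy in a class-coded way (Roman-numeral
peak classes): Val62 distinguishes position-1 occupancy (II vs I), Lys63
distinguishes position 1 / position 2 / neither (III / IV / V, mirrored by
His45 as VI / VII / VIII), and Ala49/Tyr78 distinguish a uronic acid at
position 7 (IX) from a chain ending with a HexNAc at position 6 (X).
Observed class sets therefore constrain which registers an oligomer can
occupy; inference keeps the candidates consistent with every reporter and
then selects the minimal set of registers that jointly explain all observed
classes, breaking ties by interaction score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Iterable, Optional

from .glycan_builder import GlycanSequence, parse_sequence

H_THRESHOLD = 0.05  # ppm, amide proton significance (strict >)
N_THRESHOLD = 0.20  # ppm, amide nitrogen significance (strict >)


class CSPError(ValueError):
    pass


# ---------------------------------------------------------------------------
# peak lists (Sparky-style text)


@dataclass
class PeakList:
    """Sparky-style 2-D peak list: label, w1 (heavy nucleus), w2 (1H)."""

    entries: dict[str, tuple[float, float]]
    nuclei: str = "15N"  # heavy dimension: '15N' or '13C'

    def __len__(self) -> int:
        return len(self.entries)


def read_peaklist(path, nuclei: Optional[str] = None) -> PeakList:
    """Parse a whitespace-delimited peak list: ``label  w1  w2`` per line.

    An ``Assignment``/``w1`` header line is skipped; a ``# nuclei:`` comment
    sets the heavy-dimension tag unless overridden by the argument.
    """
    entries: dict[str, tuple[float, float]] = {}
    tag = nuclei
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                if key.strip().lower() == "nuclei" and nuclei is None:
                    tag = value.strip()
                continue
            parts = line.split()
            if parts[0].lower() in ("assignment",):
                continue
            if len(parts) < 3:
                raise CSPError(f"malformed peak line: {line!r}")
            label = parts[0]
            try:
                w1, w2 = float(parts[1]), float(parts[2])
            except ValueError as exc:
                raise CSPError(f"non-numeric shift in line: {line!r}") from exc
            if label in entries:
                raise CSPError(f"duplicate assignment label {label!r}")
            entries[label] = (w1, w2)
    return PeakList(entries=entries, nuclei=tag or "15N")


def write_peaklist(peaks: PeakList, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# nuclei: {peaks.nuclei}\n")
        fh.write("Assignment  w1  w2\n")
        for label, (w1, w2) in peaks.entries.items():
            fh.write(f"{label}  {w1:.3f}  {w2:.3f}\n")


@dataclass
class DeltaShift:
    label: str
    delta_h: float
    delta_heavy: float
    significant_h: bool
    significant_heavy: bool


@dataclass
class DeltaShiftResult:
    shifts: list[DeltaShift]
    unmatched_reference: list[str]
    unmatched_complex: list[str]

    def significant(self) -> list[DeltaShift]:
        return [s for s in self.shifts if s.significant_h or s.significant_heavy]


def delta_shifts(reference: PeakList, complex_: PeakList,
                 h_threshold: float = H_THRESHOLD,
                 heavy_threshold: float = N_THRESHOLD) -> DeltaShiftResult:
    """Per-label shift differences, complex minus reference.

    A dimension is flagged significant when |delta| strictly exceeds its
    threshold (a value exactly at threshold is not significant). Labels
    present in only one list are reported, not silently dropped.
    """
    if reference.nuclei != complex_.nuclei:
        raise CSPError(
            f"nucleus tag mismatch: {reference.nuclei!r} vs {complex_.nuclei!r}"
        )
    shifts = []
    for label, (w1r, w2r) in reference.entries.items():
        if label not in complex_.entries:
            continue
        w1c, w2c = complex_.entries[label]
        dheavy = w1c - w1r
        dh = w2c - w2r
        shifts.append(
            DeltaShift(
                label=label,
                delta_h=dh,
                delta_heavy=dheavy,
                significant_h=abs(dh) > h_threshold,
                significant_heavy=abs(dheavy) > heavy_threshold,
            )
        )
    matched = {s.label for s in shifts}
    return DeltaShiftResult(
        shifts=shifts,
        unmatched_reference=[l for l in reference.entries if l not in matched],
        unmatched_complex=[l for l in complex_.entries if l not in matched],
    )


# ---------------------------------------------------------------------------
# groove and registers


DEFAULT_FEATURES: dict[int, tuple[str, ...]] = {
    1: ("His45 stack", "Lys63 salt bridge"),
    2: ("Cys47/Cys68 van der Waals",),
    3: ("Lys11 salt bridge",),
    4: ("Ile61 methyl pocket", "Tyr12 H-bond"),
    5: ("Tyr59 stack",),
    6: ("Tyr78 stack", "Tyr78 H-bond", "methyl pocket"),
    7: ("Arg81 salt bridge",),
    8: (),
}


@dataclass(frozen=True)
class GrooveModel:
    """Eight-position binding groove; odd positions hold uronic acids."""

    n_positions: int = 8
    features: dict[int, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_FEATURES)
    )
    max_overhang: int = 2
    min_in_groove: int = 4

    def uronic_position(self, p: int) -> bool:
        return p % 2 == 1

    def feature_count(self, p: int) -> int:
        return len(self.features.get(p, ()))


@dataclass(frozen=True)
class Register:
    """Placement of an oligomer with ring r at groove position offset + r."""

    oligomer: GlycanSequence
    offset: int
    groove: GrooveModel

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(self.offset + r for r in range(1, len(self.oligomer) + 1))

    @property
    def occupied(self) -> frozenset[int]:
        return frozenset(
            p for p in self.positions if 1 <= p <= self.groove.n_positions
        )

    @property
    def overhang_nonreducing(self) -> int:
        return sum(1 for p in self.positions if p < 1)

    @property
    def overhang_reducing(self) -> int:
        return sum(1 for p in self.positions if p > self.groove.n_positions)

    @property
    def reducing_position(self) -> int:
        return self.offset + len(self.oligomer)

    @property
    def score(self) -> int:
        """Count of groove interaction features satisfied by occupancy."""
        return sum(self.groove.feature_count(p) for p in self.occupied)

    def describe(self) -> str:
        return (
            f"{self.oligomer.spec or 'oligomer'} at positions "
            f"{self.positions[0]}-{self.positions[-1]} "
            f"(in-groove {sorted(self.occupied)}, score {self.score})"
        )


def enumerate_registers(oligomer: GlycanSequence,
                        groove: Optional[GrooveModel] = None) -> list[Register]:
    """All placements satisfying parity, overhang and occupancy rules.

    Parity: every in-groove ring's class must match its position (odd =
    uronic acid). Overhang is limited to ``groove.max_overhang`` rings per
    end and at least ``groove.min_in_groove`` rings must sit in the groove.
    """
    groove = groove or GrooveModel()
    n = len(oligomer)
    out = []
    for offset in range(-n, groove.n_positions + 1):
        reg = Register(oligomer, offset, groove)
        if reg.overhang_nonreducing > groove.max_overhang:
            continue
        if reg.overhang_reducing > groove.max_overhang:
            continue
        if len(reg.occupied) < groove.min_in_groove:
            continue
        ok = True
        for r in range(1, n + 1):
            p = offset + r
            if 1 <= p <= groove.n_positions:
                if groove.uronic_position(p) != (oligomer.ring_class(r) == "uronic"):
                    ok = False
                    break
        if ok:
            out.append(reg)
    return out


# ---------------------------------------------------------------------------
# reporter rules


def _rule_val62(reg: Register) -> Optional[str]:
    return "II" if 1 in reg.occupied else "I"


def _rule_lys63(reg: Register) -> Optional[str]:
    if 1 in reg.occupied:
        return "III"
    if 2 in reg.occupied:
        return "IV"
    return "V"


def _rule_his45(reg: Register) -> Optional[str]:
    # mirrors the Lys63 pattern with its own class labels
    if 1 in reg.occupied:
        return "VI"
    if 2 in reg.occupied:
        return "VII"
    return "VIII"


def _rule_ala49(reg: Register) -> Optional[str]:
    if 7 in reg.occupied:
        return "IX"
    if reg.reducing_position == 6:
        return "X"
    return None  # unclassified: imposes no constraint


@dataclass
class ReporterRuleTable:
    """Occupancy predicates mapping each reporter residue to a peak class."""

    rules: dict[str, Callable[[Register], Optional[str]]] = field(
        default_factory=lambda: {
            "Val62": _rule_val62,
            "Lys63": _rule_lys63,
            "Ala49": _rule_ala49,
        }
    )

    def with_his45(self) -> "ReporterRuleTable":
        rules = dict(self.rules)
        rules["His45"] = _rule_his45
        return ReporterRuleTable(rules)

    def reporters(self) -> list[str]:
        return list(self.rules)


def predict_classes(register: Register,
                    rules: Optional[ReporterRuleTable] = None) -> dict[str, Optional[str]]:
    """Deterministic per-reporter class label (None = unclassified)."""
    rules = rules or ReporterRuleTable()
    return {name: fn(register) for name, fn in rules.rules.items()}


@dataclass
class InferenceResult:
    registers: list[Register]
    explanations: list[str]
    uncovered_classes: set[str]
    rejected: list[tuple[Register, str]]

    @property
    def n_registers(self) -> int:
        return len(self.registers)


def infer_registers(oligomer: GlycanSequence,
                    groove: Optional[GrooveModel] = None,
                    rules: Optional[ReporterRuleTable] = None,
                    observed: Optional[dict[str, Iterable[str]]] = None) -> InferenceResult:
    """Select the registers consistent with observed per-reporter class sets.

    A candidate is consistent when, for every reporter with a nonempty
    observed set, its predicted class is either within the observed set or
    unclassified (which imposes no constraint). Among consistent candidates
    the minimal subset whose predictions jointly cover all coverable
    observed classes is selected; ties go to the higher total interaction
    score, then to the lower offsets for determinism. Observed classes no
    candidate can produce are reported as uncovered, never silently dropped.
    """
    groove = groove or GrooveModel()
    rules = rules or ReporterRuleTable()
    observed = {k: set(v) for k, v in (observed or {}).items() if v}
    if not observed:
        raise CSPError("observed class sets are empty for every reporter")

    candidates = enumerate_registers(oligomer, groove)
    consistent: list[Register] = []
    rejected: list[tuple[Register, str]] = []
    for reg in candidates:
        predicted = predict_classes(reg, rules)
        violation = None
        for reporter, obs in observed.items():
            label = predicted.get(reporter)
            if label is not None and label not in obs:
                violation = (
                    f"{reporter}: predicted {label}, observed {sorted(obs)}"
                )
                break
        if violation is None:
            consistent.append(reg)
        else:
            rejected.append((reg, violation))

    observed_union = set().union(*observed.values())
    predictable = set()
    pred_by_reg: dict[int, set[str]] = {}
    for reg in consistent:
        labels = {v for v in predict_classes(reg, rules).values() if v is not None}
        pred_by_reg[reg.offset] = labels
        predictable |= labels
    coverable = observed_union & predictable
    uncovered = observed_union - predictable

    best: Optional[tuple[int, int, tuple[int, ...], tuple[Register, ...]]] = None
    for size in range(1, len(consistent) + 1):
        for combo in combinations(consistent, size):
            covered = set().union(*(pred_by_reg[r.offset] for r in combo)) if combo else set()
            if coverable <= covered:
                key = (
                    size,
                    -sum(r.score for r in combo),
                    tuple(sorted(r.offset for r in combo)),
                    combo,
                )
                if best is None or key[:3] < best[:3]:
                    best = key
        if best is not None:
            break

    selected = sorted(best[3], key=lambda r: r.offset) if best else []
    explanations = [
        r.describe() + f" -> {predict_classes(r, rules)}" for r in selected
    ]
    if not selected:
        explanations = [
            f"no consistent register: {reg.describe()} violated {why}"
            for reg, why in rejected
        ]
    return InferenceResult(
        registers=selected,
        explanations=explanations,
        uncovered_classes=uncovered,
        rejected=rejected,
    )


# ---------------------------------------------------------------------------
# full-fill analysis


HA_FAMILY = (
    "HA4^AN", "HA4^NA", "HA5^AA", "HA5^NN",
    "HA6^AN", "HA6^NA", "HA7^AA", "HA7^NN",
    "HA8^AN", "HA8^NA",
)


def full_fill_length(groove: Optional[GrooveModel] = None,
                     family: Iterable[str] = HA_FAMILY,
                     positions_to_cover: Optional[frozenset[int]] = None
                     ) -> tuple[int, list[str]]:
    """Shortest family member with a register covering the stated positions.

    The default coverage target is the interacting span, positions 1-7 (the
    eighth position carries no interaction feature). Returns the minimal ring
    count and every witnessing oligomer of that length.
    """
    groove = groove or GrooveModel()
    if positions_to_cover is None:
        positions_to_cover = frozenset(range(1, 8))
    by_length: dict[int, list[str]] = {}
    for spec in family:
        seq = parse_sequence(spec)
        for reg in enumerate_registers(seq, groove):
            if positions_to_cover <= reg.occupied:
                by_length.setdefault(len(seq), []).append(spec)
                break
    if not by_length:
        raise CSPError("no family member covers the requested positions")
    n = min(by_length)
    return n, sorted(set(by_length[n]))


# ---------------------------------------------------------------------------
# canonical peak-class shift table (shared with the synthetic panel generator)

#: free-peak positions (15N ppm, 1H ppm) for the reporter amides
REPORTER_FREE_PEAKS: dict[str, tuple[float, float]] = {
    "Val62": (121.30, 8.25),
    "Lys63": (118.50, 7.90),
    "Ala49": (124.70, 8.45),
    "His45": (115.20, 7.40),
}

#: Sparky-style assignment label roots for the reporters
REPORTER_LABELS: dict[str, str] = {
    "Val62": "V62N-H",
    "Lys63": "K63N-H",
    "Ala49": "A49N-H",
    "His45": "H45N-H",
}

#: class -> (d15N, d1H) offsets from the free peak. Arbitrary fixed constants
#: spaced >= 5x the significance thresholds so classes are unambiguous at
#: zero noise.
CLASS_SHIFTS: dict[str, dict[str, tuple[float, float]]] = {
    "Val62": {"I": (1.20, 0.30), "II": (-1.20, -0.30)},
    "Lys63": {"III": (2.00, 0.50), "IV": (-2.00, 0.50), "V": (0.00, -0.50)},
    "Ala49": {"IX": (1.50, 0.35), "X": (-1.50, -0.35)},
    "His45": {"VI": (1.00, 0.30), "VII": (-1.00, -0.30), "VIII": (2.20, -0.30)},
}


def classify_observed_peaks(reference: PeakList, complex_: PeakList,
                            reporters: Optional[Iterable[str]] = None,
                            h_threshold: float = H_THRESHOLD,
                            heavy_threshold: float = N_THRESHOLD
                            ) -> dict[str, set[str]]:
    """Read per-reporter observed class sets from a free/complex peak pair.

    Complex peaks for a reporter (the label root, plus any suffixed copies
    for multi-register species) are assigned to the nearest canonical class
    position in threshold-scaled shift space; peaks that did not move
    significantly contribute no class.
    """
    reporters = list(reporters or REPORTER_FREE_PEAKS)
    out: dict[str, set[str]] = {}
    for rep in reporters:
        root = REPORTER_LABELS[rep]
        free = reference.entries.get(root)
        if free is None:
            continue
        classes: set[str] = set()
        for label, (w1, w2) in complex_.entries.items():
            if not label.startswith(root):
                continue
            dn = w1 - free[0]
            dh = w2 - free[1]
            if abs(dn) <= heavy_threshold and abs(dh) <= h_threshold:
                continue  # unshifted
            best_cls, best_d = None, None
            for cls, (cn, ch) in CLASS_SHIFTS[rep].items():
                d = ((dn - cn) / heavy_threshold) ** 2 + ((dh - ch) / h_threshold) ** 2
                if best_d is None or d < best_d:
                    best_cls, best_d = cls, d
            if best_cls is not None:
                classes.add(best_cls)
        out[rep] = classes
    return out
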