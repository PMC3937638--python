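"""Peak lists, shift perturbations, register enumeration and inference."""

import numpy as np
import pytest

from linkgag.csp_register import (
    CSPError,
    GrooveModel,
    PeakList,
    Register,
    ReporterRuleTable,
    delta_shifts,
    enumerate_registers,
    full_fill_length,
    infer_registers,
    predict_classes,
    read_peaklist,
    write_peaklist,
)
from linkgag.glycan_builder import parse_sequence

GROOVE = GrooveModel()


def register_set(spec):
    return {r.offset for r in enumerate_registers(parse_sequence(spec), GROOVE)}


# ---------------------------------------------------------------------------
# peak-list parsing


def test_read_single_entry(tmp_path):
    p = tmp_path / "one.list"
    p.write_text("Assignment w1 w2\nV62N-H 121.30 8.25\n")
    peaks = read_peaklist(p)
    assert len(peaks) == 1
    assert peaks.entries["V62N-H"] == (121.30, 8.25)


def test_read_empty_file(tmp_path):
    p = tmp_path / "empty.list"
    p.write_text("")
    assert len(read_peaklist(p)) == 0


def test_duplicate_label_rejected(tmp_path):
    p = tmp_path / "dup.list"
    p.write_text("V62N-H 121.30 8.25\nV62N-H 120.00 8.00\n")
    with pytest.raises(CSPError, match="duplicate"):
        read_peaklist(p)


def test_non_numeric_shift_rejected(tmp_path):
    p = tmp_path / "bad.list"
    p.write_text("V62N-H x 8.25\n")
    with pytest.raises(CSPError, match="non-numeric"):
        read_peaklist(p)


def test_peaklist_write_read_round_trip(tmp_path):
    peaks = PeakList({"V62N-H": (121.3, 8.25), "K63N-H": (118.5, 7.9)},
                     nuclei="15N")
    p = tmp_path / "rt.list"
    write_peaklist(peaks, p)
    back = read_peaklist(p)
    assert back.nuclei == "15N"
    assert back.entries.keys() == peaks.entries.keys()


# ---------------------------------------------------------------------------
# delta shifts


def test_identical_lists_give_zero_deltas():
    peaks = PeakList({"V62N-H": (121.3, 8.25)}, nuclei="15N")
    res = delta_shifts(peaks, peaks)
    assert res.shifts[0].delta_h == 0.0
    assert not res.significant()


def test_carbon_ring_reporter_deltas():
    """The 13C-labeled ring reporter: bound minus free on C1-H1."""
    free = PeakList({"C1-H1": (103.50, 4.47)}, nuclei="13C")
    bound = PeakList({"C1-H1": (103.50 - 1.30, 4.47 + 0.14)}, nuclei="13C")
    res = delta_shifts(free, bound, h_threshold=0.05, heavy_threshold=0.20)
    s = res.shifts[0]
    assert s.delta_heavy == pytest.approx(-1.30)
    assert s.delta_h == pytest.approx(+0.14)
    assert s.significant_heavy and s.significant_h


def test_threshold_boundary_is_strict():
    # binary-exact offsets so the at-threshold case is not blurred by
    # floating-point representation
    ref = PeakList({"A49N-H": (124.0, 8.0)}, nuclei="15N")
    cpx = PeakList({"A49N-H": (124.0 + 0.25, 8.0 + 0.0625)}, nuclei="15N")
    s = delta_shifts(ref, cpx, h_threshold=0.0625, heavy_threshold=0.25).shifts[0]
    assert not s.significant_h and not s.significant_heavy
    cpx2 = PeakList({"A49N-H": (124.0 + 0.26, 8.0 + 0.07)}, nuclei="15N")
    s2 = delta_shifts(ref, cpx2, h_threshold=0.0625, heavy_threshold=0.25).shifts[0]
    assert s2.significant_h and s2.significant_heavy


def test_delta_shifts_antisymmetric():
    rng = np.random.default_rng(9)
    a = PeakList({f"R{i}N-H": tuple(rng.normal(size=2)) for i in range(6)})
    b = PeakList({f"R{i}N-H": tuple(rng.normal(size=2)) for i in range(6)})
    fwd = {s.label: (s.delta_heavy, s.delta_h) for s in delta_shifts(a, b).shifts}
    rev = {s.label: (s.delta_heavy, s.delta_h) for s in delta_shifts(b, a).shifts}
    for label in fwd:
        assert fwd[label][0] == pytest.approx(-rev[label][0])
        assert fwd[label][1] == pytest.approx(-rev[label][1])


def test_nucleus_mismatch_rejected():
    a = PeakList({"X": (1.0, 2.0)}, nuclei="15N")
    b = PeakList({"X": (1.0, 2.0)}, nuclei="13C")
    with pytest.raises(CSPError, match="mismatch"):
        delta_shifts(a, b)


def test_unmatched_labels_reported():
    a = PeakList({"X": (1.0, 2.0), "Y": (3.0, 4.0)})
    b = PeakList({"X": (1.0, 2.0), "Z": (5.0, 6.0)})
    res = delta_shifts(a, b)
    assert res.unmatched_reference == ["Y"]
    assert res.unmatched_complex == ["Z"]


# ---------------------------------------------------------------------------
# register enumeration (brute-force oracle)


def brute_force_offsets(spec, groove=GROOVE):
    """Independent enumeration: scan every placement, apply the stated rules."""
    seq = parse_sequence(spec)
    n = len(seq)
    keep = set()
    for offset in range(-30, 30):
        positions = [offset + r for r in range(1, n + 1)]
        in_groove = [p for p in positions if 1 <= p <= groove.n_positions]
        over_nr = sum(p < 1 for p in positions)
        over_red = sum(p > groove.n_positions for p in positions)
        if over_nr > 2 or over_red > 2 or len(in_groove) < 4:
            continue
        parity_ok = all(
            (p % 2 == 1) == (seq.ring_class(p - offset) == "uronic")
            for p in in_groove
        )
        if parity_ok:
            keep.add(offset)
    return keep


@pytest.mark.parametrize("spec", [
    "HA4^AN", "HA4^NA", "HA5^AA", "HA5^NN", "HA6^AN", "HA6^NA",
    "HA7^AA", "HA7^NN", "HA8^AN", "HA8^NA", "HA10^AN", "C8",
])
def test_enumeration_matches_brute_force(spec):
    assert register_set(spec) == brute_force_offsets(spec)


def test_ha7nn_candidate_placements():
    """HA7^NN admits three placements: spans 0-6, 2-8 and 4-10."""
    regs = sorted(enumerate_registers(parse_sequence("HA7^NN"), GROOVE),
                  key=lambda r: r.offset)
    spans = [(r.positions[0], r.positions[-1]) for r in regs]
    assert spans == [(0, 6), (2, 8), (4, 10)]


def test_register_parity_invariant_exhaustive():
    for spec in ("HA8^AN", "HA7^NN", "HA6^NA", "HA5^AA", "HA4^NA"):
        for reg in enumerate_registers(parse_sequence(spec), GROOVE):
            for p in reg.occupied:
                ring = p - reg.offset
                assert (p % 2 == 1) == (reg.oligomer.ring_class(ring) == "uronic")
            assert reg.overhang_nonreducing <= 2
            assert reg.overhang_reducing <= 2
            assert len(reg.occupied) >= 4


# ---------------------------------------------------------------------------
# class prediction


def test_predicted_classes_for_full_length_octamer():
    reg = Register(parse_sequence("HA8^AN"), 0, GROOVE)
    assert predict_classes(reg) == {"Val62": "II", "Lys63": "III", "Ala49": "IX"}


def test_predicted_classes_for_short_oligomer_midgroove():
    reg = Register(parse_sequence("HA5^AA"), 2, GROOVE)  # positions 3-7
    got = predict_classes(reg)
    assert got["Lys63"] == "V"
    assert got["Ala49"] == "IX"
    assert got["Val62"] == "I"


def test_unclassified_when_no_predicate_holds():
    reg = Register(parse_sequence("HA4^NA"), 1, GROOVE)  # positions 2-5
    assert predict_classes(reg)["Ala49"] is None


def test_his45_mirror_rule():
    rules = ReporterRuleTable().with_his45()
    reg = Register(parse_sequence("HA8^AN"), 0, GROOVE)
    assert predict_classes(reg, rules)["His45"] == "VI"
    reg2 = Register(parse_sequence("HA5^AA"), 2, GROOVE)
    assert predict_classes(reg2, rules)["His45"] == "VIII"


def test_rules_mutually_exclusive_and_exhaustive():
    """Across every enumerated register of the panel, each reporter maps to
    exactly one label (or unclassified, for Ala49 only)."""
    for spec in ("HA4^AN", "HA5^NN", "HA6^AN", "HA7^AA", "HA8^NA"):
        for reg in enumerate_registers(parse_sequence(spec), GROOVE):
            got = predict_classes(reg)
            assert got["Val62"] in ("I", "II")
            assert got["Lys63"] in ("III", "IV", "V")
            assert got["Ala49"] in ("IX", "X", None)


# ---------------------------------------------------------------------------
# inference


def test_dual_register_heptamer():
    result = infer_registers(
        parse_sequence("HA7^NN"),
        observed={"Val62": {"I", "II"}, "Lys63": {"III", "IV"},
                  "Ala49": {"IX", "X"}},
    )
    assert result.n_registers == 2
    spans = sorted((r.positions[0], r.positions[-1]) for r in result.registers)
    assert spans == [(0, 6), (2, 8)]
    assert not result.uncovered_classes


def test_hexamer_binds_at_one_to_six():
    result = infer_registers(
        parse_sequence("HA6^AN"),
        observed={"Val62": {"II"}, "Lys63": {"III"}, "Ala49": {"X"}},
    )
    assert result.n_registers == 1
    reg = result.registers[0]
    assert (reg.positions[0], reg.positions[-1]) == (1, 6)
    assert reg.reducing_position == 6


def test_pentamer_tie_broken_by_interaction_score():
    """Both 3-7 and 5-9 are consistent with {I, V, IX}; the feature-richer
    3-7 placement wins the tie."""
    result = infer_registers(
        parse_sequence("HA5^AA"),
        observed={"Val62": {"I"}, "Lys63": {"V"}, "Ala49": {"IX"}},
    )
    assert result.n_registers == 1
    assert (result.registers[0].positions[0], result.registers[0].positions[-1]) == (3, 7)


def test_octamer_unique_after_inference():
    result = infer_registers(
        parse_sequence("HA8^AN"),
        observed={"Val62": {"II"}, "Lys63": {"III"}, "Ala49": {"IX"}},
    )
    assert result.n_registers == 1
    assert result.registers[0].offset == 0


def test_inconsistent_observation_yields_diagnostics():
    result = infer_registers(
        parse_sequence("HA8^AN"),
        observed={"Val62": {"I"}, "Lys63": {"V"}, "Ala49": {"X"}},
    )
    assert result.registers == []
    assert result.rejected  # every candidate named with its first violation
    assert any("Val62" in why or "Lys63" in why for _, why in result.rejected)


def test_empty_observations_rejected():
    with pytest.raises(CSPError, match="empty"):
        infer_registers(parse_sequence("HA8^AN"), observed={})


# ---------------------------------------------------------------------------
# full fill


def test_full_fill_minimal_length_is_seven():
    n, witnesses = full_fill_length()
    assert n == 7
    assert witnesses == ["HA7^AA"]


def test_full_fill_degenerate_targets():
    n, _ = full_fill_length(positions_to_cover=frozenset())
    assert n == 4
    n8, witnesses8 = full_fill_length(positions_to_cover=frozenset(range(1, 9)))
    assert n8 == 8
    assert witnesses8 == ["HA8^AN"]
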