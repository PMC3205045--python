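import random

import pytest

from chemtagger.dataparser import (
    FormulaError,
    Peak,
    Tolerances,
    check_consistency,
    find_data,
    mass_percent,
    monoisotopic_mass,
    parse_formula,
    parse_peak_list,
    render_peak_list,
)
from chemtagger.fixtures import random_peaks

# frozen reference masses: 6*12 + 6*1.0078250319 etc., summed independently
C6H6_MASS = 6 * 12.0 + 6 * 1.0078250319
H2O_MASS = 2 * 1.0078250319 + 15.9949146221


# ---------------------------------------------------------------------------
# Formulae and masses
# ---------------------------------------------------------------------------

def test_parse_formula():
    assert parse_formula("C7H8") == {"C": 7, "H": 8}
    assert parse_formula("CH4") == {"C": 1, "H": 4}
    assert parse_formula("C2H6O") == {"C": 2, "H": 6, "O": 1}


@pytest.mark.parametrize("bad", ["", "c7h8", "C7H8Qq9", "7CH"])
def test_bad_formulae_rejected(bad):
    with pytest.raises(FormulaError):
        parse_formula(bad)


def test_monoisotopic_masses_against_hand_sums():
    assert monoisotopic_mass(parse_formula("C6H6")) == pytest.approx(
        C6H6_MASS, abs=1e-9
    )
    assert round(monoisotopic_mass(parse_formula("C6H6")), 4) == 78.0470
    assert round(monoisotopic_mass(parse_formula("H2O")), 4) == 18.0106
    with pytest.raises(FormulaError):
        monoisotopic_mass({})


def test_mass_additivity():
    rng = random.Random(5)
    elements = ["C", "H", "N", "O", "S", "Cl"]
    for _ in range(50):
        f1 = {el: rng.randint(1, 20) for el in rng.sample(elements, 3)}
        f2 = {el: rng.randint(1, 20) for el in rng.sample(elements, 3)}
        merged = {
            el: f1.get(el, 0) + f2.get(el, 0) for el in set(f1) | set(f2)
        }
        assert monoisotopic_mass(merged) == pytest.approx(
            monoisotopic_mass(f1) + monoisotopic_mass(f2), abs=1e-9
        )


def test_mass_percent_sums_to_100():
    pct = mass_percent(parse_formula("C7H8"))
    assert sum(pct.values()) == pytest.approx(100.0)
    assert pct["C"] == pytest.approx(91.25, abs=0.01)


# ---------------------------------------------------------------------------
# Locating and parsing annotations
# ---------------------------------------------------------------------------

def test_simple_hnmr():
    text = "1H NMR (400 MHz, CDCl3) δ 7.26 (s, 1H)."
    (ann,) = find_data(text)
    assert ann.kind == "HNMR"
    assert ann.payload["peaks"] == [Peak(shift=7.26, multiplicity="s", integration=1)]
    assert text[ann.start : ann.end] == ann.surface


def test_no_cues_no_annotations():
    assert find_data("Plain chemistry prose without data.") == []


def test_bare_delta_peak_list_with_range():
    text = "δ 2.36 (s, 3H), 7.26–7.17 (m, 5H)"
    (ann,) = find_data(text)
    assert ann.payload["peaks"] == [
        Peak(shift=2.36, multiplicity="s", integration=3),
        Peak(shift=(7.26, 7.17), multiplicity="m", integration=5),
    ]


def test_couplings_parsed():
    (ann,) = find_data("δ 1.20 (d, J = 7.0, 2.1 Hz, 6H)")
    (peak,) = ann.payload["peaks"]
    assert peak.couplings == (7.0, 2.1)


def test_cnmr_and_hnmr_spans_do_not_overlap():
    text = (
        "13C NMR (101 MHz, CDCl3) δ 21.4, 125.3, 129.0. "
        "1H NMR (400 MHz, CDCl3) δ 2.36 (s, 3H)."
    )
    anns = find_data(text)
    assert [a.kind for a in anns] == ["CNMR", "HNMR"]
    assert anns[0].payload["shifts"] == [21.4, 125.3, 129.0]
    assert anns[0].end <= anns[1].start


def test_hrms_parsing():
    (ann,) = find_data("HRMS (ESI) calcd for C7H7+ 91.0542, found 91.0540.")
    assert ann.kind == "HRMS"
    assert ann.payload["formula"] == "C7H7"
    assert ann.payload["calcd"] == 91.0542
    assert ann.payload["found"] == 91.0540


def test_elemental_parsing():
    (ann,) = find_data(
        "Anal. Calcd for C7H8: C, 91.25; H, 8.75. Found: C, 91.02; H, 8.81."
    )
    assert ann.kind == "ELEMENTAL"
    assert ann.payload["calcd"] == {"C": 91.25, "H": 8.75}
    assert ann.payload["found"] == {"C": 91.02, "H": 8.81}


def test_unknown_element_flags_unparsed_instead_of_raising():
    (ann,) = find_data("HRMS (ESI) calcd for C7Qq8 91.0542, found 91.0540.")
    assert ann.kind == "HRMS"
    assert not ann.parsed
    assert check_consistency(ann, parse_formula("C7H8")) == []


# ---------------------------------------------------------------------------
# Round trip
# ---------------------------------------------------------------------------

def test_peak_list_round_trip_random():
    rng = random.Random(77)
    for _ in range(200):
        peaks = random_peaks(rng, rng.randint(1, 8))
        rendered = render_peak_list(peaks)
        assert parse_peak_list(rendered) == peaks
        (ann,) = find_data(rendered)
        assert ann.kind == "HNMR"
        assert ann.payload["peaks"] == peaks


# ---------------------------------------------------------------------------
# Consistency checks
# ---------------------------------------------------------------------------

def toluene_hnmr(h1, h2):
    return find_data(f"1H NMR (400 MHz, CDCl3) δ 7.20 (m, {h1}H), 2.36 (s, {h2}H).")[0]


def test_toluene_integration_pass_and_fail():
    f = parse_formula("C7H8")
    (ok,) = check_consistency(toluene_hnmr(5, 3), f)
    assert ok.passed and ok.observed == 8.0

    (bad,) = check_consistency(toluene_hnmr(4, 3), f)
    assert not bad.passed
    assert bad.observed == 7.0 and bad.expected == 8.0


def test_hrms_checks():
    mass = monoisotopic_mass(parse_formula("C6H6"))
    (ann,) = find_data(f"HRMS (EI) calcd for C6H6 {mass:.4f}, found {mass + 0.0003:.4f}.")
    calcd, ppm = check_consistency(ann, None)
    assert calcd.check == "hrms_calcd_mass" and calcd.passed
    assert ppm.check == "hrms_found_ppm" and ppm.passed

    (off,) = find_data("HRMS (EI) calcd for C6H6 78.1470, found 78.1470.")
    calcd, _ = check_consistency(off, None)
    assert not calcd.passed


def test_hrms_ppm_tolerance_boundary():
    (ann,) = find_data("HRMS (EI) calcd for C6H6 78.0470, found 78.0480.")
    _, ppm = check_consistency(ann, None, Tolerances(ppm=5.0))
    assert not ppm.passed  # ~12.8 ppm deviation
    _, ppm_loose = check_consistency(ann, None, Tolerances(ppm=20.0))
    assert ppm_loose.passed


def test_elemental_checks_within_tolerance():
    (ann,) = find_data(
        "Anal. Calcd for C7H8: C, 91.25; H, 8.75. Found: C, 91.02; H, 8.81."
    )
    reports = check_consistency(ann, None)
    assert len(reports) == 4
    assert all(r.passed for r in reports)

    (bad,) = find_data(
        "Anal. Calcd for C7H8: C, 91.25; H, 8.75. Found: C, 89.90; H, 8.81."
    )
    found_c = [r for r in check_consistency(bad, None) if r.check == "elemental_found_C"]
    assert not found_c[0].passed
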