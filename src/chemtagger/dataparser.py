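"""Recognition, parsing and checking of stylised experimental data.

Synthetic chemistry papers report characterisation data in rigid,
journal-mandated strings — ``1H NMR (400 MHz, CDCl3) δ 7.26 (s, 1H), ...``,
``HRMS (ESI) calcd for C7H7+ 91.0542, found 91.0545`` or ``Anal. Calcd for
C7H8: C, 91.25; H, 8.75. Found: ...``.  This module locates such spans with
data-driven regular expressions, parses them into structured annotations and
runs elementary consistency checks against a molecular formula: proton
integrals must sum to the hydrogen count, the printed HRMS calculated mass
must equal the monoisotopic mass of the stated ion formula, and printed
elemental percentages must match the computed mass percentages.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources as importlib_resources

# ---------------------------------------------------------------------------
# Atomic masses
# ---------------------------------------------------------------------------

def _load_masses() -> tuple[dict[str, float], dict[str, float]]:
    text = (
        importlib_resources.files("chemtagger.resources")
        .joinpath("atomic_masses.csv")
        .read_text("utf-8")
    )
    mono: dict[str, float] = {}
    avg: dict[str, float] = {}
    for row in csv.DictReader(text.splitlines()):
        mono[row["element"]] = float(row["monoisotopic_mass"])
        avg[row["element"]] = float(row["average_mass"])
    return mono, avg


MONOISOTOPIC_MASSES, AVERAGE_MASSES = _load_masses()


# ---------------------------------------------------------------------------
# Molecular formulae
# ---------------------------------------------------------------------------

class FormulaError(ValueError):
    pass


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
FORMULA_RE = r"(?:[A-Z][a-z]?\d*)+"


def parse_formula(text: str) -> dict[str, int]:
    """Parse a Hill-order formula string ("C7H8") into element counts."""
    if not text or not re.fullmatch(FORMULA_RE, text):
        raise FormulaError(f"malformed molecular formula: {text!r}")
    counts: dict[str, int] = {}
    for element, digits in _FORMULA_TOKEN.findall(text):
        if element not in MONOISOTOPIC_MASSES:
            raise FormulaError(f"unknown element {element!r} in formula {text!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
    return counts


def monoisotopic_mass(formula: dict[str, int]) -> float:
    """Sum of exact masses of each element's principal isotope, in Da."""
    if not formula:
        raise FormulaError("empty formula")
    try:
        return sum(MONOISOTOPIC_MASSES[el] * n for el, n in formula.items())
    except KeyError as exc:
        raise FormulaError(f"unknown element {exc.args[0]!r}") from exc


def mass_percent(formula: dict[str, int]) -> dict[str, float]:
    """Mass-percent composition using standard (average) atomic weights."""
    if not formula:
        raise FormulaError("empty formula")
    total = sum(AVERAGE_MASSES[el] * n for el, n in formula.items())
    return {el: 100.0 * AVERAGE_MASSES[el] * n / total for el, n in formula.items()}


# ---------------------------------------------------------------------------
# Peaks and annotations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Peak:
    """One NMR resonance: shift in ppm (value or range), multiplicity,
    optional proton integration and J couplings in Hz."""

    shift: float | tuple[float, float]
    multiplicity: str
    integration: int | None = None
    couplings: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.integration is not None and self.integration < 1:
            raise ValueError("integration must be >= 1")


@dataclass(frozen=True)
class DataAnnotation:
    """A located experimental-data span with its parsed payload."""

    kind: str  # HNMR | CNMR | HRMS | ELEMENTAL
    surface: str
    start: int
    end: int
    payload: dict
    parsed: bool = True


# --- grammar (a journal-style dialect, kept as data so users can extend) ----

_NUM = r"\d+(?:\.\d+)?"
_SHIFT = rf"-?{_NUM}"
_DASH = r"[–−-]"  # en dash, minus sign or hyphen for shift ranges
_J = rf"J\s*=\s*{_NUM}(?:\s*,\s*{_NUM})*\s*Hz"
_PEAK = (
    rf"({_SHIFT})(?:\s*{_DASH}\s*({_SHIFT}))?\s*"
    rf"\(\s*([a-z]+)\s*(?:,\s*({_J}))?\s*(?:,\s*(\d+)\s*H)?\s*\)"
)
_PEAK_RE = re.compile(_PEAK)
_PEAK_LIST = rf"(?:{_PEAK})(?:\s*,\s*(?:{_PEAK}))*"

HNMR_RE = re.compile(
    rf"(?:(?:1H|¹H)\s*NMR\s*(?:\([^)]*\))?\s*)?δ\s*{_PEAK_LIST}"
)
CNMR_RE = re.compile(
    rf"(?:13C|¹³C)\s*NMR\s*(?:\([^)]*\))?\s*δ\s*"
    rf"{_SHIFT}(?:\s*,\s*{_SHIFT})*"
)
HRMS_RE = re.compile(
    rf"HRMS\s*(?:\([^)]*\))?\s*(?:m/z\s*)?:?\s*calcd\.?\s+for\s+"
    rf"({FORMULA_RE})\s*([+\-]|\[[^\]]*\][+\-]?)?\s*,?\s*({_NUM})\s*,\s*"
    rf"found\s*:?\s*({_NUM})"
)
ELEMENTAL_RE = re.compile(
    rf"Anal\.\s*Calcd\.?\s+for\s+({FORMULA_RE})\s*:\s*"
    rf"((?:[A-Z][a-z]?\s*,\s*{_NUM}\s*[;.]?\s*)+?)"
    rf"Found\s*:\s*((?:[A-Z][a-z]?\s*,\s*{_NUM}\s*[;.]?\s*)*[A-Z][a-z]?\s*,\s*{_NUM})"
)

_ELEMENT_PAIR = re.compile(rf"([A-Z][a-z]?)\s*,\s*({_NUM})")


def parse_peak_list(text: str) -> list[Peak]:
    """Parse a comma-separated 1H-style peak list."""
    peaks = []
    for m in _PEAK_RE.finditer(text):
        lo, hi, mult, jgroup, integ = m.groups()
        shift: float | tuple[float, float] = (
            (float(lo), float(hi)) if hi is not None else float(lo)
        )
        couplings: tuple[float, ...] = ()
        if jgroup:
            inner = jgroup[jgroup.index("=") + 1 : jgroup.lower().rindex("hz")]
            couplings = tuple(float(x) for x in re.findall(_NUM, inner))
        peaks.append(
            Peak(
                shift=shift,
                multiplicity=mult,
                integration=int(integ) if integ else None,
                couplings=couplings,
            )
        )
    return peaks


def render_peak_list(peaks: list[Peak]) -> str:
    """Render peaks in the canonical dialect (inverse of the peak grammar)."""
    parts = []
    for p in peaks:
        if isinstance(p.shift, tuple):
            shift = f"{p.shift[0]:.2f}–{p.shift[1]:.2f}"
        else:
            shift = f"{p.shift:.2f}"
        inner = [p.multiplicity]
        if p.couplings:
            inner.append("J = " + ", ".join(f"{j:.1f}" for j in p.couplings) + " Hz")
        if p.integration is not None:
            inner.append(f"{p.integration}H")
        parts.append(f"{shift} ({', '.join(inner)})")
    return "δ " + ", ".join(parts)


def find_data(text: str) -> list[DataAnnotation]:
    """Locate and parse all experimental-data spans in a document.

    Kinds are matched in the order HRMS, ELEMENTAL, CNMR, HNMR; spans never
    overlap (earlier kinds shadow later ones).  A located span whose payload
    cannot be interpreted is returned flagged ``parsed=False`` instead of
    raising.
    """
    annotations: list[DataAnnotation] = []
    claimed: list[tuple[int, int]] = []

    def free(s: int, e: int) -> bool:
        return all(min(e, ce) <= max(s, cs) for cs, ce in claimed)

    for kind, pattern in (
        ("HRMS", HRMS_RE),
        ("ELEMENTAL", ELEMENTAL_RE),
        ("CNMR", CNMR_RE),
        ("HNMR", HNMR_RE),
    ):
        for m in pattern.finditer(text):
            if not free(m.start(), m.end()):
                continue
            payload: dict = {}
            parsed = True
            try:
                if kind == "HRMS":
                    formula, ion, calcd, found = m.groups()
                    payload = {
                        "formula": formula,
                        "ion": ion or "",
                        "calcd": float(calcd),
                        "found": float(found),
                    }
                    parse_formula(formula)
                elif kind == "ELEMENTAL":
                    formula, calcd_seg, found_seg = m.groups()
                    payload = {
                        "formula": formula,
                        "calcd": {
                            el: float(v) for el, v in _ELEMENT_PAIR.findall(calcd_seg)
                        },
                        "found": {
                            el: float(v) for el, v in _ELEMENT_PAIR.findall(found_seg)
                        },
                    }
                    parse_formula(formula)
                elif kind == "CNMR":
                    body = m.group(0)
                    shifts = body[body.index("δ") + 1 :]
                    payload = {"shifts": [float(x) for x in re.findall(_NUM, shifts)]}
                else:  # HNMR
                    payload = {"peaks": parse_peak_list(m.group(0))}
            except (FormulaError, ValueError) as exc:
                parsed = False
                payload = {"error": str(exc)}
            annotations.append(
                DataAnnotation(
                    kind=kind,
                    surface=m.group(0),
                    start=m.start(),
                    end=m.end(),
                    payload=payload,
                    parsed=parsed,
                )
            )
            claimed.append((m.start(), m.end()))
    annotations.sort(key=lambda a: a.start)
    return annotations


# ---------------------------------------------------------------------------
# Consistency checks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Tolerances:
    """Check tolerances: HRMS mass window (Da), HRMS found-vs-calcd window
    (ppm) and elemental-analysis window (percentage points)."""

    mass_da: float = 0.005
    ppm: float = 5.0
    elemental_pct: float = 0.4


@dataclass(frozen=True)
class ConsistencyReport:
    check: str
    passed: bool
    observed: float
    expected: float
    tolerance: float


def check_consistency(
    ann: DataAnnotation,
    formula: dict[str, int] | None = None,
    tolerances: Tolerances = Tolerances(),
) -> list[ConsistencyReport]:
    """Run the elementary structure-consistency checks for one annotation.

    ``formula`` is the molecular formula of the reported compound (used for
    the proton-integral check); HRMS and elemental checks use the formula
    stated inside the annotation itself.  Unparsed annotations are skipped
    (empty report list), never failed.
    """
    if not ann.parsed:
        return []
    reports: list[ConsistencyReport] = []

    if ann.kind == "HNMR" and formula is not None:
        total = sum(p.integration or 0 for p in ann.payload["peaks"])
        expected = formula.get("H", 0)
        reports.append(
            ConsistencyReport(
                check="hnmr_integration",
                passed=total == expected,
                observed=float(total),
                expected=float(expected),
                tolerance=0.0,
            )
        )
    elif ann.kind == "HRMS":
        ion_formula = parse_formula(ann.payload["formula"])
        calcd, found = ann.payload["calcd"], ann.payload["found"]
        expected_mass = monoisotopic_mass(ion_formula)
        reports.append(
            ConsistencyReport(
                check="hrms_calcd_mass",
                passed=abs(calcd - expected_mass) <= tolerances.mass_da,
                observed=calcd,
                expected=expected_mass,
                tolerance=tolerances.mass_da,
            )
        )
        ppm = abs(found - calcd) / calcd * 1e6
        reports.append(
            ConsistencyReport(
                check="hrms_found_ppm",
                passed=ppm <= tolerances.ppm,
                observed=found,
                expected=calcd,
                tolerance=tolerances.ppm,
            )
        )
    elif ann.kind == "ELEMENTAL":
        computed = mass_percent(parse_formula(ann.payload["formula"]))
        for label in ("calcd", "found"):
            for el, printed in ann.payload[label].items():
                expected = computed.get(el)
                if expected is None:
                    reports.append(
                        ConsistencyReport(
                            check=f"elemental_{label}_{el}",
                            passed=False,
                            observed=printed,
                            expected=0.0,
                            tolerance=tolerances.elemental_pct,
                        )
                    )
                    continue
                reports.append(
                    ConsistencyReport(
                        check=f"elemental_{label}_{el}",
                        passed=abs(printed - expected) <= tolerances.elemental_pct,
                        observed=printed,
                        expected=expected,
                        tolerance=tolerances.elemental_pct,
                    )
                )
    return reports
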