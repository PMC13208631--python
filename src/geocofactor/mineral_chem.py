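"""Mineral formula parsing and electronegativity statistics.

The central quantity is the weighted Mineral Element Electronegativity
Coefficient of Variation (wMEE_CV): the atom-count-weighted sample standard
deviation of a mineral's per-atom Pauling electronegativities divided by
their weighted mean.  For oregonite, FeNi2As2, the five per-atom values
1.83, 1.91, 1.91, 2.18, 2.18 give SD 0.166, mean 2.002 and wMEE_CV 0.083.

Cohort-level comparisons use the hard-acid/base range ratio (MHR): for a
given metal, the range of wMEE_CV among its minerals that contain a hard
acid or hard base, divided by the range among those that do not (the
metallic native element contributes wMEE_CV = 0 to the latter).
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from typing import Iterable, Mapping

__all__ = [
    "ElementInfo",
    "FormulaError",
    "MHRResult",
    "MineralFormula",
    "MineralRecord",
    "atom_en_values",
    "load_element_table",
    "load_hsab_table",
    "mhr",
    "parse_formula",
    "read_mineral_table",
    "render_formula",
    "wmee_cv",
]

# All IUPAC element symbols; used only to validate tokens during parsing.
ELEMENT_SYMBOLS = frozenset(
    """H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co
    Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te
    I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir
    Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No
    Lr Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og""".split()
)

HSAB_CLASSES = frozenset(
    {"hard_acid", "hard_base", "soft_acid", "soft_base", "intermediate", "none"}
)


class FormulaError(ValueError):
    """Raised when a nominal formula cannot be parsed."""


@dataclass(frozen=True)
class ElementInfo:
    """Pauling electronegativity and HSAB class for one element."""

    symbol: str
    pauling_en: float
    hsab_class: str = "none"

    def __post_init__(self) -> None:
        if self.pauling_en <= 0:
            raise ValueError(f"pauling_en must be > 0, got {self.pauling_en}")
        if self.hsab_class not in HSAB_CLASSES:
            raise ValueError(f"unknown HSAB class {self.hsab_class!r}")


@dataclass(frozen=True)
class MineralFormula:
    """Parsed element→count stoichiometry of a nominal IMA formula.

    Counts are positive rationals; fractional counts arise from
    shared-occupancy sites such as ``(Fe,Ni)9``.
    """

    name: str
    raw: str
    counts: Mapping[str, Fraction]

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("counts must be non-empty")
        for sym, c in self.counts.items():
            if c <= 0:
                raise ValueError(f"count for {sym} must be > 0, got {c}")

    @property
    def total_atoms(self) -> Fraction:
        return sum(self.counts.values(), Fraction(0))


@dataclass
class MineralRecord:
    """One mineral species with its age, locality weight and derived stats."""

    formula: MineralFormula
    max_age_ga: float
    locality_count: int
    wmee_cv: float
    has_hard_acid_base: bool

    @classmethod
    def from_formula(
        cls,
        formula: MineralFormula,
        table: Mapping[str, ElementInfo],
        max_age_ga: float = 0.0,
        locality_count: int = 1,
    ) -> "MineralRecord":
        """Build a record, deriving wMEE_CV and the hard-acid/base flag."""
        hab = any(
            table[sym].hsab_class in ("hard_acid", "hard_base")
            for sym in formula.counts
            if sym in table
        )
        return cls(
            formula=formula,
            max_age_ga=max_age_ga,
            locality_count=locality_count,
            wmee_cv=wmee_cv(formula, table),
            has_hard_acid_base=hab,
        )


@dataclass(frozen=True)
class MHRResult:
    """Hard-acid/base wMEE_CV range ratio for one metal."""

    metal: str
    range_with_hab: float
    range_without_hab: float
    ratio: float


# ---------------------------------------------------------------------------
# bundled tables
# ---------------------------------------------------------------------------


def _data_text(filename: str) -> str:
    return (resources.files("geocofactor") / "data" / filename).read_text()


def _read_tsv(filename: str) -> list[dict[str, str]]:
    lines = [
        ln for ln in _data_text(filename).splitlines() if ln and not ln.startswith("#")
    ]
    return list(csv.DictReader(lines, delimiter="\t"))


def load_hsab_table() -> dict[str, str]:
    """Element symbol → HSAB class, from the bundled (editable) table."""
    return {row["symbol"]: row["hsab_class"] for row in _read_tsv("hsab_classes.tsv")}


def load_element_table() -> dict[str, ElementInfo]:
    """Bundled Pauling electronegativities merged with HSAB classes.

    Elements with no accepted Pauling value are absent; looking them up
    raises rather than imputing.
    """
    hsab = load_hsab_table()
    table = {}
    for row in _read_tsv("pauling_electronegativity.tsv"):
        sym = row["symbol"]
        table[sym] = ElementInfo(
            symbol=sym,
            pauling_en=float(row["pauling_en"]),
            hsab_class=hsab.get(sym, "none"),
        )
    return table


# ---------------------------------------------------------------------------
# formula grammar
# ---------------------------------------------------------------------------
#
#   formula   := part ( ('·' | '*') coeff? part )*        hydration dots
#   part      := unit+
#   unit      := (element | group) subscript?
#   group     := '(' part (',' part)* ')'                 comma = shared site
#   subscript := number ('/' number)? variable?           "9", "0.5", "10/3"
#   variable  := ('+' | '-') number? 'x'                  "1+x" at nominal x
#
# A comma group distributes the site multiplicity equally among its members:
# (Fe,Ni)9 → Fe 9/2, Ni 9/2.  A plain '.' is accepted as a hydration dot
# only when followed by an optional integer and H2O (the common CSV export
# style "FeSO4.7H2O"); elsewhere '.' is a decimal point, as in "Fe0.5O".

_NUM_RE = re.compile(r"\d+(?:\.\d+)?")
_VAR_RE = re.compile(r"([+-])(\d+(?:\.\d+)?)?x")
_HYDRATE_DOT_RE = re.compile(r"\.(?=\d*H2O)")


class _Parser:
    def __init__(self, text: str, x: float) -> None:
        self.text = text
        self.pos = 0
        self.x = Fraction(str(x))

    def error(self, msg: str) -> FormulaError:
        return FormulaError(f"{msg} at position {self.pos} in {self.text!r}")

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def parse(self) -> dict[str, Fraction]:
        counts = self._part(top=True)
        if self.pos != len(self.text):
            raise self.error(f"unexpected character {self.peek()!r}")
        return counts

    def _part(self, top: bool = False) -> dict[str, Fraction]:
        counts: dict[str, Fraction] = {}
        saw_unit = False
        while self.pos < len(self.text):
            ch = self.peek()
            if ch in "·*":
                if not top:
                    break
                self.pos += 1
                coeff = self._number() or Fraction(1)
                _merge(counts, self._part(), coeff)
                saw_unit = True
                continue
            if ch == "(":
                _merge(counts, *self._group())
                saw_unit = True
                continue
            if ch.isalpha():
                sym = self._element()
                sub = self._subscript()
                _merge(counts, {sym: Fraction(1)}, sub)
                saw_unit = True
                continue
            break
        if not saw_unit:
            raise self.error("expected an element symbol or group")
        return counts

    def _group(self) -> tuple[dict[str, Fraction], Fraction]:
        start = self.pos
        self.pos += 1  # consume '('
        members = [self._part()]
        while self.peek() == ",":
            self.pos += 1
            members.append(self._part())
        if self.peek() != ")":
            self.pos = start
            raise self.error("unbalanced parentheses")
        self.pos += 1
        mult = self._subscript()
        counts: dict[str, Fraction] = {}
        share = Fraction(1, len(members))  # equal split of a shared site
        for m in members:
            _merge(counts, m, share if len(members) > 1 else Fraction(1))
        return counts, mult

    def _element(self) -> str:
        sym = self.peek()
        self.pos += 1
        if self.peek().islower():
            sym += self.peek()
            self.pos += 1
        if sym not in ELEMENT_SYMBOLS:
            raise self.error(f"unknown element symbol {sym!r}")
        return sym

    def _number(self) -> Fraction | None:
        m = _NUM_RE.match(self.text, self.pos)
        if not m:
            return None
        self.pos = m.end()
        return Fraction(m.group())

    def _subscript(self) -> Fraction:
        num = self._number()
        if num is None:
            return Fraction(1)
        if self.peek() == "/":
            self.pos += 1
            den = self._number()
            if den is None:
                raise self.error("expected denominator after '/'")
            num /= den
        m = _VAR_RE.match(self.text, self.pos)
        if m:
            self.pos = m.end()
            coeff = Fraction(m.group(2)) if m.group(2) else Fraction(1)
            num += (coeff if m.group(1) == "+" else -coeff) * self.x
        return num


def _merge(
    into: dict[str, Fraction], other: Mapping[str, Fraction], mult: Fraction = Fraction(1)
) -> None:
    for sym, c in other.items():
        into[sym] = into.get(sym, Fraction(0)) + c * mult


def parse_formula(text: str, name: str = "", x: float = 0.0) -> MineralFormula:
    """Parse a nominal mineral formula into element counts.

    Parameters
    ----------
    text:
        Formula string, e.g. ``"FeNi2As2"``, ``"(Fe,Ni)9S8"`` or
        ``"Ca3Fe2(SiO4)3"``.  Comma groups split the site multiplicity
        equally among the listed elements; hydration dots add the water
        stoichiometry; variable terms like ``(Fe,Ni)1+xS`` are evaluated at
        the nominal ``x`` (default 0, the end-member).
    name:
        Optional mineral name carried on the result.
    x:
        Nominal value for variable stoichiometry terms.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula")
    cleaned = _HYDRATE_DOT_RE.sub("·", text.strip())
    counts = _Parser(cleaned, x).parse()
    return MineralFormula(name=name or text.strip(), raw=text, counts=counts)


def render_formula(formula: MineralFormula) -> str:
    """Render counts back to the flat grammar (fractions as ``a/b``)."""
    parts = []
    for sym, c in formula.counts.items():
        if c == 1:
            parts.append(sym)
        elif c.denominator == 1:
            parts.append(f"{sym}{c.numerator}")
        else:
            parts.append(f"{sym}{c.numerator}/{c.denominator}")
    return "".join(parts)


# ---------------------------------------------------------------------------
# electronegativity statistics
# ---------------------------------------------------------------------------


def atom_en_values(
    formula: MineralFormula, table: Mapping[str, ElementInfo]
) -> list[tuple[float, float]]:
    """Per-element (electronegativity, atom-count weight) pairs.

    Expanding the integer weights reproduces the per-atom value list; for
    oregonite that is 1.83, 1.91, 1.91, 2.18, 2.18.
    """
    pairs = []
    for sym, count in formula.counts.items():
        if sym not in table:
            raise KeyError(
                f"element {sym!r} has no Pauling electronegativity in the table"
            )
        pairs.append((table[sym].pauling_en, float(count)))
    return pairs


def wmee_cv(formula: MineralFormula, table: Mapping[str, ElementInfo]) -> float:
    """Weighted electronegativity coefficient of variation of one mineral.

    The weighted sample standard deviation uses frequency weights with a
    ``W − 1`` divisor (W = total atom count), which reduces to the ordinary
    n−1 sample formula when the formula is expanded into an explicit atom
    list.  Single-element formulas (metallic Fe, Ni) return exactly 0.
    """
    pairs = atom_en_values(formula, table)
    if len(pairs) == 1:
        return 0.0
    w_total = sum(w for _, w in pairs)
    if w_total <= 1:
        return 0.0
    mean = sum(en * w for en, w in pairs) / w_total
    var = sum(w * (en - mean) ** 2 for en, w in pairs) / (w_total - 1)
    return math.sqrt(var) / mean


def mhr(records: Iterable[MineralRecord], metal: str) -> MHRResult:
    """Hard-acid/base wMEE_CV range ratio for one metal's minerals.

    The numerator is the max−min wMEE_CV range over records flagged as
    containing a hard acid or hard base; the denominator the range over the
    remainder (where the native metallic record contributes its 0).
    """
    recs = [r for r in records if metal in r.formula.counts]
    with_hab = [r.wmee_cv for r in recs if r.has_hard_acid_base]
    without_hab = [r.wmee_cv for r in recs if not r.has_hard_acid_base]
    if not with_hab:
        raise ValueError(f"no {metal} records in the hard-acid/base stratum")
    if not without_hab:
        raise ValueError(f"no {metal} records in the no-hard-acid/base stratum")
    range_with = max(with_hab) - min(with_hab)
    range_without = max(without_hab) - min(without_hab)
    if range_without == 0:
        raise ValueError(
            f"{metal} no-hard-acid/base stratum has zero wMEE_CV range; "
            "ratio undefined"
        )
    return MHRResult(
        metal=metal,
        range_with_hab=range_with,
        range_without_hab=range_without,
        ratio=range_with / range_without,
    )


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------


def read_mineral_table(
    path, table: Mapping[str, ElementInfo] | None = None
) -> list[MineralRecord]:
    """Read a mineral CSV/TSV into records with derived statistics.

    Expected columns: ``mineral_name``, ``formula``, ``max_age_ga``,
    ``locality_count`` (extra columns are ignored).  The delimiter is
    sniffed from the header line.
    """
    import pandas as pd

    if table is None:
        table = load_element_table()
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    required = {"mineral_name", "formula", "max_age_ga", "locality_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mineral table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        formula = parse_formula(str(row.formula), name=str(row.mineral_name))
        records.append(
            MineralRecord.from_formula(
                formula,
                table,
                max_age_ga=float(row.max_age_ga),
                locality_count=int(row.locality_count),
            )
        )
    return records
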