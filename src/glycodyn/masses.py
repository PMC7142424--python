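"""Exact monoisotopic mass arithmetic for small-molecule mass spectrometry.

Provides elemental formulas with Hill-order parsing, adduct/ion m/z
conventions (proton-based, electron mass included), signed ppm deviations,
and exhaustive brute-force enumeration of C/H/O formulas inside a ppm
window around an observed m/z.

Ion m/z convention
------------------
For an adduct ``[xM + delta]^z`` the theoretical m/z is

    m/z = (x * M_neutral + m(delta) - z * m_e) / |z|

i.e. the electron mass is accounted for explicitly, so ``[M-H]-`` equals
the neutral mass minus the mass of a proton.  This level of care is needed
to reproduce sub-0.01-ppm deviations of high-resolution instruments.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Mapping, Tuple

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "ElementalFormula",
    "AdductSpec",
    "ADDUCTS",
    "FormulaConstraints",
    "monoisotopic_mass",
    "theoretical_mz",
    "ppm_deviation",
    "enumerate_formulas",
]

#: CODATA/IUPAC monoisotopic atomic masses (Da).
MONOISOTOPIC_MASS: Dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "O": 15.9949146196,
    "N": 14.0030740048,
    "S": 31.97207100,
    "Na": 22.9897692809,
}

ELECTRON_MASS = 0.00054857990907
# m/z convention: the "proton" is a hydrogen atom minus an electron, so that
# deprotonation (delta -H, charge -1) subtracts exactly one proton mass.
# Differs from the CODATA free proton only by the H binding energy (~1.5e-8 Da).
PROTON_MASS = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS

_ELEMENT_ORDER = ("C", "H", "N", "Na", "O", "S")  # Hill order for CH-containing formulas
_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """An immutable multiset of element counts.

    Counts are non-negative integers; the all-zero formula is legal and has
    mass zero.  Addition and subtraction are element-wise; subtraction that
    would produce a negative count raises ``ValueError``.
    """

    counts: Tuple[Tuple[str, int], ...]

    def __init__(self, counts: Mapping[str, int] | None = None, **kw: int):
        merged: Dict[str, int] = {}
        for src in (counts or {}), kw:
            for el, n in src.items():
                if el not in MONOISOTOPIC_MASS:
                    raise ValueError(f"unknown element symbol: {el!r}")
                if int(n) != n or n < 0:
                    raise ValueError(f"element count must be a non-negative integer: {el}={n}")
                if n:
                    merged[el] = merged.get(el, 0) + int(n)
        object.__setattr__(
            self, "counts", tuple(sorted(merged.items(), key=lambda kv: _hill_key(kv[0])))
        )

    # -- mapping-ish access -------------------------------------------------
    def __getitem__(self, el: str) -> int:
        return dict(self.counts).get(el, 0)

    def items(self) -> Iterator[Tuple[str, int]]:
        return iter(self.counts)

    def as_dict(self) -> Dict[str, int]:
        return dict(self.counts)

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        out = self.as_dict()
        for el, n in other.items():
            out[el] = out.get(el, 0) + n
        return ElementalFormula(out)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        out = self.as_dict()
        for el, n in other.items():
            out[el] = out.get(el, 0) - n
            if out[el] < 0:
                raise ValueError(
                    f"subtraction produces a negative {el} count: {self} - {other}"
                )
        return ElementalFormula(out)

    def __mul__(self, k: int) -> "ElementalFormula":
        if int(k) != k or k < 0:
            raise ValueError("formula multiplier must be a non-negative integer")
        return ElementalFormula({el: n * int(k) for el, n in self.items()})

    __rmul__ = __mul__

    def __bool__(self) -> bool:
        return bool(self.counts)

    # -- properties ---------------------------------------------------------
    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    @property
    def dbe(self) -> float:
        """Rings plus double bonds: C - H/2 + N/2 + 1 (O and S neutral)."""
        return self["C"] - self["H"] / 2 + self["N"] / 2 + 1

    # -- text ---------------------------------------------------------------
    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse a Hill-order formula string such as ``"C76H120O42"``."""
        text = text.strip()
        if text in ("", "0"):
            return cls({})
        pos = 0
        counts: Dict[str, int] = {}
        for m in _FORMULA_TOKEN.finditer(text):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r} at position {pos}")
            el, num = m.group(1), m.group(2)
            if el not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element symbol: {el!r} in {text!r}")
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
            pos = m.end()
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        return cls(counts)

    def __str__(self) -> str:
        return "".join(f"{el}{n if n != 1 else ''}" for el, n in self.counts) or ""

    def __repr__(self) -> str:
        return f"ElementalFormula({str(self)!r})"


def _hill_key(el: str) -> Tuple[int, str]:
    try:
        return (_ELEMENT_ORDER.index(el), el)
    except ValueError:
        return (len(_ELEMENT_ORDER), el)


def monoisotopic_mass(formula: ElementalFormula | Mapping[str, int] | str) -> float:
    """Monoisotopic mass in Da of a neutral composition (0 for the empty formula)."""
    if isinstance(formula, str):
        formula = ElementalFormula.parse(formula)
    elif not isinstance(formula, ElementalFormula):
        formula = ElementalFormula(formula)
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in formula.items())


@dataclass(frozen=True)
class AdductSpec:
    """Ion species formed from ``multimer`` neutral molecules.

    ``delta`` holds signed element-count changes (e.g. ``{"H": -1}`` for
    deprotonation); ``charge`` is the signed charge of the ion.
    """

    name: str
    multimer: int
    delta: Tuple[Tuple[str, int], ...]
    charge: int

    def __init__(self, name: str, multimer: int, delta: Mapping[str, int], charge: int):
        if multimer < 1:
            raise ValueError("multimer count must be >= 1")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "multimer", int(multimer))
        object.__setattr__(self, "delta", tuple(sorted(delta.items())))
        object.__setattr__(self, "charge", int(charge))

    @property
    def delta_mass(self) -> float:
        return sum(MONOISOTOPIC_MASS[el] * n for el, n in self.delta)

    def mz(self, neutral_mass: float) -> float:
        if self.charge == 0:
            raise ValueError(f"adduct {self.name!r} has charge 0; |charge| >= 1 required")
        ion_mass = self.multimer * neutral_mass + self.delta_mass - self.charge * ELECTRON_MASS
        return ion_mass / abs(self.charge)

    def neutral_mass(self, mz: float) -> float:
        """Invert :meth:`mz`: the neutral monomer mass implied by an observed m/z."""
        if self.charge == 0:
            raise ValueError(f"adduct {self.name!r} has charge 0; |charge| >= 1 required")
        return (mz * abs(self.charge) - self.delta_mass + self.charge * ELECTRON_MASS) / self.multimer


#: Built-in adduct dialect (every ion label used in the saponin/flavonoid tables).
ADDUCTS: Dict[str, AdductSpec] = {
    a.name: a
    for a in [
        AdductSpec("[M-H]-", 1, {"H": -1}, -1),
        AdductSpec("[M+H]+", 1, {"H": 1}, +1),
        AdductSpec("[M+Na]+", 1, {"Na": 1}, +1),
        AdductSpec("[M+NH4]+", 1, {"N": 1, "H": 4}, +1),
        AdductSpec("[M-H+FA]-", 1, {"C": 1, "H": 1, "O": 2}, -1),
        AdductSpec("[M-H+NaFA]-", 1, {"C": 1, "H": 0, "Na": 1, "O": 2}, -1),
        AdductSpec("[2M-H]-", 2, {"H": -1}, -1),
        AdductSpec("[2M+Na]+", 2, {"Na": 1}, +1),
        AdductSpec("[M-2H]2-", 1, {"H": -2}, -2),
    ]
}


def theoretical_mz(
    formula: ElementalFormula | str,
    adduct: AdductSpec | str = "[M-H]-",
    *,
    composition: str = "neutral",
) -> float:
    """Theoretical m/z of ``formula`` under ``adduct``.

    ``composition="neutral"`` (default) treats the formula as the neutral
    molecule and applies the adduct contract.  ``composition="ion"`` treats
    the formula as the ion's own elemental composition; the adduct then only
    supplies the charge (m/z = mass(formula) - z*m_e over |z|), the way
    vendor software reports "sum formulas" of already-charged fragments.
    """
    if isinstance(formula, str):
        formula = ElementalFormula.parse(formula)
    if isinstance(adduct, str):
        adduct = ADDUCTS[adduct]
    if composition == "neutral":
        return adduct.mz(monoisotopic_mass(formula))
    if composition == "ion":
        if adduct.charge == 0:
            raise ValueError("|charge| >= 1 required")
        return (monoisotopic_mass(formula) - adduct.charge * ELECTRON_MASS) / abs(adduct.charge)
    raise ValueError(f"composition must be 'neutral' or 'ion', got {composition!r}")


def ppm_deviation(observed_mz: float, theoretical: float) -> float:
    """Signed relative deviation (observed - theoretical) / theoretical * 1e6."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed_mz - theoretical) / theoretical * 1e6


@dataclass(frozen=True)
class FormulaConstraints:
    """Search box for CHO formula enumeration.

    ``composition="neutral"`` enumerates neutral molecules whose adduct m/z
    matches; DBE integrality then enforces even hydrogen counts.
    ``composition="ion"`` enumerates the ion composition directly (vendor
    convention), where half-integer DBE values are legal.
    """

    c_range: Tuple[int, int] = (0, 150)
    h_range: Tuple[int, int] = (0, 300)
    o_range: Tuple[int, int] = (0, 80)
    dbe_min: float = 0.0
    dbe_max: float = 100.0
    integer_dbe: bool = True
    composition: str = "neutral"

    def __post_init__(self):
        for lo, hi in (self.c_range, self.h_range, self.o_range):
            if hi is None:
                raise ValueError("unbounded constraints rejected: every element needs a max")

    @classmethod
    def default(cls) -> "FormulaConstraints":
        return cls()

    @classmethod
    def vendor(cls) -> "FormulaConstraints":
        """Xcalibur-style box: ion composition, RDBE in [-1, 100], no parity rule.

        This is the configuration under which the observed precursor at
        m/z 1703.71838 admits exactly 19 C/H/O assignments at 5 ppm.
        """
        return cls(
            c_range=(0, 150),
            h_range=(0, 300),
            o_range=(0, 100),
            dbe_min=-1.0,
            dbe_max=100.0,
            integer_dbe=False,
            composition="ion",
        )


def enumerate_formulas(
    observed_mz: float,
    adduct: AdductSpec | str = "[M-H]-",
    tol_ppm: float = 5.0,
    constraints: FormulaConstraints | None = None,
) -> List[Tuple[ElementalFormula, float]]:
    """All CHO formulas whose theoretical m/z lies within ``tol_ppm`` of the
    observation, sorted by absolute ppm deviation.

    The search is an exhaustive bounded iteration over carbon and oxygen
    counts with the admissible hydrogen window solved per (C, O) pair, which
    is provably equivalent to the full triple loop over the constraint box.
    """
    if tol_ppm < 0:
        raise ValueError("tol_ppm must be >= 0")
    if isinstance(adduct, str):
        adduct = ADDUCTS[adduct]
    cons = constraints or FormulaConstraints.default()

    if cons.composition == "neutral":
        # target neutral monomer mass implied by the observation
        ref_mass = adduct.neutral_mass(observed_mz)
    else:
        # the formula IS the ion; reference its mass directly
        ref_mass = observed_mz * abs(adduct.charge) + adduct.charge * ELECTRON_MASS

    tol_da = tol_ppm * 1e-6 * observed_mz * abs(adduct.charge) * (
        adduct.multimer if cons.composition == "neutral" else 1
    )
    # NB: for multimers the ppm window on m/z maps to multimer * window on M.

    mC, mH, mO = (MONOISOTOPIC_MASS[e] for e in ("C", "H", "O"))
    out: List[Tuple[ElementalFormula, float]] = []
    for c in range(cons.c_range[0], cons.c_range[1] + 1):
        rem_after_c = ref_mass - c * mC
        if rem_after_c < -tol_da - 1:
            break
        for o in range(cons.o_range[0], cons.o_range[1] + 1):
            rem = rem_after_c - o * mO
            if rem < -tol_da - 1:
                break
            h_lo = max(cons.h_range[0], int((rem - tol_da) / mH) - 1)
            h_hi = min(cons.h_range[1], int((rem + tol_da) / mH) + 1)
            for h in range(h_lo, h_hi + 1):
                if h < 0:
                    continue
                dbe = c - h / 2 + 1
                if cons.integer_dbe and h % 2 != 0:
                    continue
                if not (cons.dbe_min <= dbe <= cons.dbe_max):
                    continue
                f = ElementalFormula({"C": c, "H": h, "O": o})
                mz = theoretical_mz(f, adduct, composition=cons.composition)
                dev = ppm_deviation(observed_mz, mz)
                if abs(mz - observed_mz) <= tol_ppm * 1e-6 * observed_mz:
                    out.append((f, dev))
    out.sort(key=lambda t: (abs(t[1]), str(t[0])))
    return out
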