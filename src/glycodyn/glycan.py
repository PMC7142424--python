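"""Glycosyl-residue decomposition and glycoside MS/MS annotation.

Saponins and flavonoid glycosides fragment in negative mode by sequential
elimination of sugar residues: neutral losses of 132 (pentosyl), 146
(deoxyhexosyl), 162 (hexosyl) and 176 Da (uronic-acid/glucuronyl) link the
precursor to aglycone-containing product ions, while the detached sugar
chain itself can appear as a deprotonated ion.  This module decomposes mass
differences into residue multisets (bounded knapsack, exhaustive) and
annotates spectra with an aglycone, a sugar composition and a per-fragment
explanation chain.

Only compositions are reported: tandem MS does not resolve linkage
positions or sugar stereochemistry, so no attempt is made to assign them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .masses import (
    ADDUCTS,
    PROTON_MASS,
    AdductSpec,
    ElementalFormula,
    monoisotopic_mass,
    ppm_deviation,
    theoretical_mz,
)

__all__ = [
    "RESIDUES",
    "AGLYCONES",
    "ResidueLibrary",
    "AglyconeLibrary",
    "FragmentExplanation",
    "SaponinAnnotation",
    "decompose_delta",
    "annotate_glycoside",
    "explain_fragment",
    "residue_multiset_mass",
    "residue_multiset_formula",
]

ResidueLibrary = Dict[str, ElementalFormula]
AglyconeLibrary = Dict[str, ElementalFormula]

#: Glycosyl residues (sugar minus water) plus small neutral losses.
RESIDUES: ResidueLibrary = {
    "pentose": ElementalFormula.parse("C5H8O4"),       # 132.04226
    "deoxyhexose": ElementalFormula.parse("C6H10O4"),  # 146.05791
    "hexose": ElementalFormula.parse("C6H10O5"),       # 162.05282
    "uronic acid": ElementalFormula.parse("C6H8O6"),   # 176.03209
}

#: Non-sugar neutral losses seen on the aglycone side.
SMALL_LOSSES: ResidueLibrary = {
    "water": ElementalFormula.parse("H2O"),            # 18.01056
    "CO2": ElementalFormula.parse("CO2"),              # 43.98983
    "acetyl": ElementalFormula.parse("C2H2O"),         # 42.01057
}

#: Aglycone cores with formula; the diagnostic deprotonated ion is derived.
AGLYCONES: AglyconeLibrary = {
    "medicagenic acid": ElementalFormula.parse("C30H46O6"),
    "zanhic acid": ElementalFormula.parse("C30H46O7"),
    "acetylated medicagenic acid": ElementalFormula.parse("C32H48O7"),
    "quercetin": ElementalFormula.parse("C15H10O7"),
    "kaempferol": ElementalFormula.parse("C15H10O6"),
    "isorhamnetin": ElementalFormula.parse("C16H12O7"),
    "apigenin": ElementalFormula.parse("C15H10O5"),
    "luteolin": ElementalFormula.parse("C15H10O6"),
}


def diagnostic_ion_mz(aglycone: str, library: AglyconeLibrary | None = None) -> float:
    """Deprotonated-aglycone m/z, the fragment diagnostic for the core."""
    lib = library or AGLYCONES
    return theoretical_mz(lib[aglycone], "[M-H]-")


def residue_multiset_mass(multiset: Mapping[str, int], library: ResidueLibrary | None = None) -> float:
    lib = library or RESIDUES
    return sum(monoisotopic_mass(lib[r]) * n for r, n in multiset.items())


def residue_multiset_formula(
    multiset: Mapping[str, int], library: ResidueLibrary | None = None
) -> ElementalFormula:
    lib = library or RESIDUES
    out = ElementalFormula({})
    for r, n in multiset.items():
        out = out + lib[r] * n
    return out


def _format_multiset(multiset: Mapping[str, int]) -> str:
    return " + ".join(f"{n}x {r}" if n > 1 else r for r, n in sorted(multiset.items())) or "none"


def decompose_delta(
    delta_mass: float,
    library: ResidueLibrary | None = None,
    tol: float = 0.01,
    max_count: int = 6,
    tol_unit: str = "Da",
    max_total: Optional[int] = None,
) -> List[Tuple[Dict[str, int], float]]:
    """All residue multisets whose summed mass matches ``delta_mass``.

    Exhaustive bounded knapsack over the library with at most ``max_count``
    copies of each residue (and optionally ``max_total`` residues overall).
    Returns ``(multiset, mass_error)`` pairs sorted by absolute error, then
    fewest residues, then lexicographic residue names (deterministic
    tie-break).  ``tol_unit`` is ``"Da"`` or ``"ppm"`` (relative to
    ``delta_mass``).  The empty multiset decomposes a delta of ~0.
    """
    if delta_mass < 0:
        raise ValueError("delta_mass must be >= 0")
    lib = library or RESIDUES
    tol_da = tol if tol_unit == "Da" else tol * 1e-6 * max(delta_mass, 1.0)
    names = sorted(lib)
    masses = [monoisotopic_mass(lib[n]) for n in names]

    out: List[Tuple[Dict[str, int], float]] = []

    def rec(i: int, remaining: float, used: int, current: Dict[str, int]) -> None:
        if remaining < -tol_da:
            return
        if i == len(names):
            if abs(remaining) <= tol_da:
                out.append((dict(current), -remaining))
            return
        m = masses[i]
        cap = max_count if max_total is None else min(max_count, max_total - used)
        for k in range(0, cap + 1):
            rem2 = remaining - k * m
            if rem2 < -tol_da:
                break
            if k:
                current[names[i]] = k
            rec(i + 1, rem2, used + k, current)
            current.pop(names[i], None)

    rec(0, delta_mass, 0, {})
    out.sort(key=lambda t: (abs(t[1]), sum(t[0].values()), tuple(sorted(t[0]))))
    return out


@dataclass
class FragmentExplanation:
    """Interpretation of a single product ion within an annotation."""

    fragment_mz: float
    kind: str  # precursor-side loss | aglycone+residues ion | sugar-chain ion |
    #            aglycone ion | aglycone-H2O-CO2 ion | unassigned
    losses: Dict[str, int] = field(default_factory=dict)
    theoretical_mz: Optional[float] = None
    ppm: Optional[float] = None

    @property
    def explained(self) -> bool:
        return self.kind != "unassigned"

    def describe(self) -> str:
        if not self.explained:
            return f"{self.fragment_mz:.5f}  unassigned"
        return (
            f"{self.fragment_mz:.5f}  {self.kind} [{_format_multiset(self.losses)}]"
            f"  ({self.ppm:+.2f} ppm)"
        )


@dataclass
class SaponinAnnotation:
    """Aglycone + sugar-residue composition explaining a glycoside spectrum."""

    aglycone: str
    aglycone_formula: ElementalFormula
    sugars: Dict[str, int]
    precursor_mz: float
    precursor_ppm: float
    fragments: List[FragmentExplanation] = field(default_factory=list)

    @property
    def neutral_formula(self) -> ElementalFormula:
        """Aglycone plus residues; element-exact by construction."""
        return self.aglycone_formula + residue_multiset_formula(self.sugars)

    @property
    def n_explained(self) -> int:
        return sum(1 for f in self.fragments if f.explained)

    @property
    def aggregate_ppm(self) -> float:
        errs = [abs(f.ppm) for f in self.fragments if f.explained] + [abs(self.precursor_ppm)]
        return sum(errs) / len(errs)

    def describe(self) -> str:
        lines = [
            f"{self.aglycone} + {_format_multiset(self.sugars)}"
            f"  (precursor {self.precursor_mz:.5f}, {self.precursor_ppm:+.2f} ppm)"
        ]
        lines += ["  " + f.describe() for f in self.fragments]
        return "\n".join(lines)


def _candidate_interpretations(
    annotation_sugars: Mapping[str, int],
    aglycone_mass: float,
    precursor_neutral_mass: float,
    residues: ResidueLibrary,
) -> List[Tuple[str, Dict[str, int], float]]:
    """(kind, losses, theoretical fragment m/z) for every explainable ion.

    All ions are singly-deprotonated.  Two views of the same cleavage exist:
    a loss of residue multiset S from the precursor equals the aglycone
    retaining the complementary multiset; the tag with the fewer residues is
    kept (loss wins ties), matching how such spectra are read.
    """
    water = monoisotopic_mass(SMALL_LOSSES["water"])
    co2 = monoisotopic_mass(SMALL_LOSSES["CO2"])
    total = sum(annotation_sugars.values())
    names = sorted(annotation_sugars)

    out: List[Tuple[str, Dict[str, int], float]] = []

    def submultisets(i: int, current: Dict[str, int]):
        if i == len(names):
            yield dict(current)
            return
        r = names[i]
        for k in range(annotation_sugars[r] + 1):
            if k:
                current[r] = k
            yield from submultisets(i + 1, current)
            current.pop(r, None)

    for sub in submultisets(0, {}):
        n_sub = sum(sub.values())
        loss_mass = residue_multiset_mass(sub, residues)
        mz = precursor_neutral_mass - loss_mass - PROTON_MASS
        if n_sub == 0:
            # the (possibly co-recorded) precursor ion itself: empty loss chain
            out.append(("precursor-side loss", {}, mz))
            continue
        if n_sub == total:
            out.append(("aglycone ion", dict(sub), mz))
        elif n_sub <= total - n_sub:
            out.append(("precursor-side loss", dict(sub), mz))
        else:
            complement = {
                r: annotation_sugars[r] - sub.get(r, 0)
                for r in annotation_sugars
                if annotation_sugars[r] - sub.get(r, 0) > 0
            }
            out.append(("aglycone+residues ion", complement, mz))
        # the detached sugar chain as a deprotonated ion (residue sum - H)
        if 0 < n_sub:
            out.append(("sugar-chain ion", dict(sub), loss_mass - PROTON_MASS))

    agl_mz = aglycone_mass - PROTON_MASS
    out.append(("aglycone-H2O-CO2 ion", {"water": 1, "CO2": 1}, agl_mz - water - co2))
    out.append(("aglycone-H2O ion", {"water": 1}, agl_mz - water))
    return out


def explain_fragment(
    fragment_mz: float,
    annotation_sugars: Mapping[str, int],
    aglycone_formula: ElementalFormula,
    precursor_neutral_mass: float,
    tol_ppm: float = 10.0,
    residues: ResidueLibrary | None = None,
) -> FragmentExplanation:
    """Best interpretation of one fragment in the context of a composition.

    Unexplainable fragments are tagged ``"unassigned"``, never dropped.
    """
    lib = residues or RESIDUES
    best: Optional[Tuple[float, str, Dict[str, int], float]] = None
    for kind, losses, mz in _candidate_interpretations(
        annotation_sugars, monoisotopic_mass(aglycone_formula), precursor_neutral_mass, lib
    ):
        if mz <= 0:
            continue
        dev = ppm_deviation(fragment_mz, mz)
        if abs(dev) <= tol_ppm and (best is None or abs(dev) < abs(best[0]) - 1e-12):
            best = (dev, kind, losses, mz)
    if best is None:
        return FragmentExplanation(fragment_mz, "unassigned")
    dev, kind, losses, mz = best
    return FragmentExplanation(fragment_mz, kind, losses, mz, dev)


def annotate_glycoside(
    precursor_mz: float,
    adduct: AdductSpec | str = "[M-H]-",
    fragment_mzs: Sequence[float] = (),
    tol_ppm: float = 10.0,
    precursor_tol_ppm: float = 5.0,
    aglycones: AglyconeLibrary | None = None,
    residues: ResidueLibrary | None = None,
    max_count: int = 6,
) -> List[SaponinAnnotation]:
    """Rank candidate (aglycone, sugar multiset) compositions for a spectrum.

    For every aglycone in the library the precursor neutral mass minus the
    aglycone mass is decomposed over the residue library at the precursor
    tolerance; each resulting composition is scored by how many fragments it
    explains (then by aggregate |ppm|).  An aglycone whose diagnostic
    deprotonated ion appears among the fragments is still subject to the
    same mass bookkeeping — the diagnostic only helps through the explained-
    fragment count.  Returns the ranked list (empty when nothing fits).
    """
    if isinstance(adduct, str):
        adduct = ADDUCTS[adduct]
    agl_lib = aglycones or AGLYCONES
    res_lib = residues or RESIDUES
    neutral = adduct.neutral_mass(precursor_mz)
    tol_da = precursor_tol_ppm * 1e-6 * precursor_mz

    lib_order = {name: i for i, name in enumerate(agl_lib)}
    out: List[SaponinAnnotation] = []
    for name, formula in agl_lib.items():
        delta = neutral - monoisotopic_mass(formula)
        if delta < -tol_da:
            continue
        for multiset, _err in decompose_delta(
            max(delta, 0.0), res_lib, tol=tol_da, max_count=max_count, tol_unit="Da"
        ):
            theo = theoretical_mz(formula + residue_multiset_formula(multiset, res_lib), adduct)
            ann = SaponinAnnotation(
                aglycone=name,
                aglycone_formula=formula,
                sugars=multiset,
                precursor_mz=precursor_mz,
                precursor_ppm=ppm_deviation(precursor_mz, theo),
            )
            ann.fragments = [
                explain_fragment(
                    f,
                    multiset,
                    formula,
                    monoisotopic_mass(ann.neutral_formula),
                    tol_ppm=tol_ppm,
                    residues=res_lib,
                )
                for f in fragment_mzs
            ]
            out.append(ann)

    # isomeric compositions with identical fragment support are ordered by
    # library position: the library lists aglycones by abundance in the
    # source material, a documented prior (MS alone cannot separate them)
    out.sort(
        key=lambda a: (
            -a.n_explained,
            round(a.aggregate_ppm, 6),
            lib_order[a.aglycone],
            tuple(sorted(a.sugars.items())),
        )
    )
    return out
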