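"""Phase I/II suspect-mass prediction and the sample-vs-control volcano screen.

Liver S9 fractions transform an aglycone by oxidative phase I chemistry
(hydroxylation, oxidation of hydroxy groups, carboxylic-acid reduction) and
conjugative phase II chemistry (glucuronidation, sulfation, acetylation,
glutathione conjugation).  ``predict_suspects`` applies these as elemental-
composition deltas breadth-first up to a depth limit, giving a suspect list
of formulas and theoretical m/z values; ``volcano_screen`` selects features
enriched in incubated samples versus quenched negative controls by fold
change and two-sample t-test; ``match_suspects`` joins the two, keeping
unmatched candidates as nontarget hits.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .masses import ADDUCTS, ElementalFormula, monoisotopic_mass, theoretical_mz

__all__ = [
    "BiotransformationRule",
    "DEFAULT_RULES",
    "SuspectEntry",
    "SuspectList",
    "VolcanoParams",
    "predict_suspects",
    "volcano_screen",
    "match_suspects",
]


@dataclass(frozen=True)
class BiotransformationRule:
    """A named elemental-composition change with its metabolic phase."""

    name: str
    delta: Tuple[Tuple[str, int], ...]  # signed element counts
    phase: str  # "I" or "II"

    def __init__(self, name: str, delta: Mapping[str, int], phase: str):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "delta", tuple(sorted(delta.items())))
        object.__setattr__(self, "phase", phase)

    def apply(self, formula: ElementalFormula) -> Optional[ElementalFormula]:
        counts = formula.as_dict()
        for el, n in self.delta:
            counts[el] = counts.get(el, 0) + n
            if counts[el] < 0:
                return None  # chemically impossible on this scaffold
        return ElementalFormula(counts)


DEFAULT_RULES: Tuple[BiotransformationRule, ...] = (
    BiotransformationRule("hydroxylation", {"O": 1}, "I"),
    BiotransformationRule("double hydroxylation", {"O": 2}, "I"),
    BiotransformationRule("oxidation of hydroxy group", {"H": -2}, "I"),
    BiotransformationRule("hydroxylation+oxidation", {"O": 1, "H": -2}, "I"),
    # carboxylic-acid reduction is chemically ambiguous; both variants emitted
    BiotransformationRule("carboxylic acid reduction (aldehyde)", {"O": -1}, "I"),
    BiotransformationRule("carboxylic acid reduction (alcohol)", {"O": -1, "H": 2}, "I"),
    BiotransformationRule("glucuronidation", {"C": 6, "H": 8, "O": 6}, "II"),
    BiotransformationRule("sulfation", {"S": 1, "O": 3}, "II"),
    BiotransformationRule("acetylation", {"C": 2, "H": 2, "O": 1}, "II"),
    # net addition after water loss; conjugation chemistry varies
    BiotransformationRule(
        "glutathione conjugation", {"C": 10, "H": 15, "N": 3, "O": 5, "S": 1}, "II"
    ),
)


@dataclass
class SuspectEntry:
    rule_path: Tuple[str, ...]  # sorted rule-name multiset
    depth: int
    formula: ElementalFormula
    mz: Dict[str, float] = field(default_factory=dict)  # adduct name -> m/z


@dataclass
class SuspectList:
    parent: ElementalFormula
    entries: List[SuspectEntry]
    truncated: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            row = {
                "rule_path": " | ".join(e.rule_path) or "parent",
                "depth": e.depth,
                "formula": str(e.formula),
                "mass": monoisotopic_mass(e.formula),
            }
            row.update({f"mz {a}": v for a, v in e.mz.items()})
            rows.append(row)
        return pd.DataFrame(rows)


def predict_suspects(
    parent: ElementalFormula | str,
    rules: Sequence[BiotransformationRule] = DEFAULT_RULES,
    max_depth: int = 3,
    max_products: int = 1000,
    adducts: Sequence[str] = ("[M-H]-", "[M+H]+"),
) -> SuspectList:
    """Breadth-first application of rule multisets up to ``max_depth``.

    Entries are keyed by the sorted multiset of applied rule names, so the
    orders {A then B} and {B then A} merge into one entry; rule deltas that
    would drive an element count negative are pruned.  Output order is
    deterministic: by depth, then lexicographic rule path.  When the number
    of products (the parent excluded) would exceed ``max_products``, the
    list is truncated in that order and flagged.
    """
    if isinstance(parent, str):
        parent = ElementalFormula.parse(parent)
    if not rules:
        raise ValueError("at least one biotransformation rule is required")

    seen: Dict[Tuple[str, ...], ElementalFormula] = {(): parent}
    frontier: List[Tuple[str, ...]] = [()]
    for depth in range(1, max_depth + 1):
        nxt: Dict[Tuple[str, ...], ElementalFormula] = {}
        for path in frontier:
            base = seen[path]
            for rule in rules:
                key = tuple(sorted(path + (rule.name,)))
                if key in seen or key in nxt:
                    continue
                f = rule.apply(base)
                if f is None:
                    continue
                nxt[key] = f
        seen.update(nxt)
        frontier = sorted(nxt)

    ordered = sorted(seen, key=lambda p: (len(p), p))
    truncated = False
    if len(ordered) - 1 > max_products:
        warnings.warn(
            f"suspect list truncated to {max_products} products", stacklevel=2
        )
        ordered = ordered[: max_products + 1]
        truncated = True

    entries = [
        SuspectEntry(
            rule_path=path,
            depth=len(path),
            formula=seen[path],
            mz={a: theoretical_mz(seen[path], a) for a in adducts},
        )
        for path in ordered
    ]
    return SuspectList(parent=parent, entries=entries, truncated=truncated)


@dataclass(frozen=True)
class VolcanoParams:
    """Selection thresholds for the nontarget screen (strict inequalities).

    ``fc_log10_threshold`` defaults to 1 (a ten-fold enrichment); the
    literal printed reading of the source workflow (log10 FC > 10, i.e. a
    pure presence/absence call) is available as configuration but is
    unattainable under the half-minimum pseudo-count rule.
    """

    p_threshold: float = 0.05
    fc_log10_threshold: float = 1.0


def volcano_screen(
    sample: pd.DataFrame,
    control: pd.DataFrame,
    params: VolcanoParams = VolcanoParams(),
) -> pd.DataFrame:
    """Per-feature fold change and Welch-free two-sample t-test on logs.

    ``sample`` and ``control`` are feature x replicate intensity frames
    sharing an index.  Missing and zero intensities are floored at the
    pseudo-count (half the smallest nonzero intensity across both arms) so
    present-vs-absent features get a finite fold change.  Returns columns
    ``fold_change``, ``log10_fc``, ``p``, ``selected``.  A feature with
    zero variance and equal means in both arms gets p = 1.
    """
    if not sample.index.equals(control.index):
        raise ValueError("sample and control frames must share the feature index")
    if sample.shape[1] < 2 or control.shape[1] < 2:
        raise ValueError("volcano screen requires >= 2 replicates per arm")
    s = sample.to_numpy(dtype=float)
    c = control.to_numpy(dtype=float)
    pooled = np.concatenate([s.ravel(), c.ravel()])
    nonzero = pooled[np.isfinite(pooled) & (pooled > 0)]
    pseudo = 0.5 * nonzero.min() if nonzero.size else 1.0
    s = np.where(np.isfinite(s) & (s > 0), s, pseudo)
    c = np.where(np.isfinite(c) & (c > 0), c, pseudo)

    fc = s.mean(axis=1) / c.mean(axis=1)
    ls, lc = np.log10(s), np.log10(c)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # zero-variance rows
        t, p = stats.ttest_ind(ls, lc, axis=1, equal_var=True)
    same = (ls.std(axis=1) == 0) & (lc.std(axis=1) == 0)
    p = np.where(same & np.isclose(ls.mean(axis=1), lc.mean(axis=1)), 1.0, p)
    p = np.where(np.isnan(p), 1.0, p)

    log10_fc = np.log10(fc)
    selected = (p < params.p_threshold) & (log10_fc > params.fc_log10_threshold)
    return pd.DataFrame(
        {"fold_change": fc, "log10_fc": log10_fc, "p": p, "selected": selected},
        index=sample.index,
    )


def match_suspects(
    candidates: pd.DataFrame,
    suspects: SuspectList,
    tol_ppm: float = 5.0,
    adduct: str = "[M-H]-",
) -> pd.DataFrame:
    """Join candidate features to suspect masses within ``tol_ppm``.

    ``candidates`` needs an ``mz`` column.  Unmatched candidates are
    retained with ``match = "nontarget hit"`` — the route by which novel
    metabolites outside the rule set are found — never dropped.
    """
    rows = []
    for fid, row in candidates.iterrows():
        mz = float(row["mz"])
        best = None
        for e in suspects.entries:
            theo = e.mz.get(adduct)
            if theo is None:
                continue
            dev = (mz - theo) / theo * 1e6
            if abs(dev) <= tol_ppm and (best is None or abs(dev) < abs(best[1])):
                best = (e, dev)
        if best is None:
            rows.append(
                {"feature": fid, "mz": mz, "match": "nontarget hit",
                 "rule_path": "", "formula": "", "ppm": np.nan}
            )
        else:
            e, dev = best
            rows.append(
                {"feature": fid, "mz": mz,
                 "match": " | ".join(e.rule_path) or "parent",
                 "rule_path": " | ".join(e.rule_path) or "parent",
                 "formula": str(e.formula), "ppm": dev}
            )
    return pd.DataFrame(
        rows, columns=["feature", "mz", "match", "rule_path", "formula", "ppm"]
    )
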