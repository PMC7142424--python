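"""Ground-truthed synthetic data with the structure the analysis assumes.

The gastrointestinal simulation emulates a three-arm longitudinal design:
extract + digestive enzymes + fecal bacteria (HEX), extract + enzymes
without bacteria (NCHEX) and a method blank with enzymes + bacteria but no
extract (MB).  Aliquots are taken before biotransformation (T0), after the
gastric (S) and small-intestinal (SI) stages and across a 2-72 h colonic
window; only the colonic stage differs between HEX and NCHEX, because the
negative control lacks fecal bacteria there and nowhere else.

Planted glycosides undergo sequential first-order deglycosylation in the
HEX colon (dI_k/dt = k_{k-1} I_{k-1} - k_k I_k along the chain), while
NCHEX holds its pre-colon level and the blank carries only matrix features.
Optional M+1 isotopologues (relative abundance 0.011 x carbon count),
multiplicative log-normal noise and a detection floor complete the tables.

What is *not* emulated: chromatographic peak shapes, retention-time drift,
ion suppression, adduct multiplicity and real fecal-matrix chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .feature_table import CLASSES, COLON_TIMES_H, PRECOLON_TIMES_H, FeatureTable
from .glycan import AGLYCONES, RESIDUES, residue_multiset_formula
from .hepatic import DEFAULT_RULES, BiotransformationRule
from .masses import ElementalFormula, theoretical_mz
from .timeseries import ISOTOPE_SPACING

__all__ = [
    "GlycosideSpec",
    "GeneratorConfig",
    "default_glycoside_library",
    "simulate_gi_experiment",
    "fragment_ladder",
    "simulate_ms2",
    "simulate_s9",
]


@dataclass(frozen=True)
class GlycosideSpec:
    """A planted glycoside and its stepwise deglycosylation programme."""

    name: str
    aglycone: str
    sugars: Tuple[Tuple[str, int], ...]
    steps: Tuple[Tuple[Tuple[str, int], ...], ...]  # residue losses per step
    rates: Tuple[float, ...]  # h^-1, one per step
    base_intensity: float = 5e6
    rt_start_min: float = 15.0
    rt_step_min: float = 1.2

    def __init__(
        self,
        name: str,
        aglycone: str,
        sugars: Mapping[str, int],
        steps: Sequence[Mapping[str, int]],
        rates: Sequence[float],
        base_intensity: float = 5e6,
        rt_start_min: float = 15.0,
        rt_step_min: float = 1.2,
    ):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "aglycone", aglycone)
        object.__setattr__(self, "sugars", tuple(sorted(sugars.items())))
        object.__setattr__(
            self, "steps", tuple(tuple(sorted(s.items())) for s in steps)
        )
        object.__setattr__(self, "rates", tuple(float(r) for r in rates))
        object.__setattr__(self, "base_intensity", float(base_intensity))
        object.__setattr__(self, "rt_start_min", float(rt_start_min))
        object.__setattr__(self, "rt_step_min", float(rt_step_min))
        if len(self.rates) != len(self.steps):
            raise ValueError("one rate constant per deglycosylation step required")
        if any(r < 0 for r in self.rates):
            raise ValueError("rate constants must be >= 0")
        remaining = dict(self.sugars)
        for step in self.steps:
            for res, n in step:
                if remaining.get(res, 0) < n:
                    raise ValueError(
                        f"step removes {res} not present in the remaining multiset"
                    )
                remaining[res] -= n
        if any(v != 0 for v in remaining.values()):
            raise ValueError("steps must consume the sugar multiset exactly")

    @property
    def n_species(self) -> int:
        return len(self.steps) + 1

    def species_sugars(self, k: int) -> Dict[str, int]:
        """Sugar multiset of species ``k`` (0 = intact glycoside)."""
        remaining = dict(self.sugars)
        for step in self.steps[:k]:
            for res, n in step:
                remaining[res] -= n
        return {r: n for r, n in remaining.items() if n > 0}

    def species_formula(self, k: int) -> ElementalFormula:
        return AGLYCONES[self.aglycone] + residue_multiset_formula(self.species_sugars(k))

    def species_mz(self, k: int, adduct: str = "[M-H]-") -> float:
        return theoretical_mz(self.species_formula(k), adduct)

    def species_rt(self, k: int) -> float:
        return self.rt_start_min + k * self.rt_step_min


def default_glycoside_library() -> List[GlycosideSpec]:
    """Three planted families: a herniariasaponin-H-like 6-species ladder,
    a 4-species ladder on the acetylated aglycone and the
    isoquercetin-to-quercetin flavonoid pair (12 features in total)."""
    return [
        GlycosideSpec(
            "hernH",
            "medicagenic acid",
            {"uronic acid": 1, "pentose": 2, "deoxyhexose": 3, "hexose": 1},
            steps=[
                {"hexose": 1},
                {"deoxyhexose": 1},
                {"pentose": 1, "deoxyhexose": 1},
                {"pentose": 1},
                {"uronic acid": 1, "deoxyhexose": 1},
            ],
            rates=[0.08, 0.09, 0.10, 0.11, 0.12],
            base_intensity=5e6,
            rt_start_min=15.3,
            rt_step_min=1.2,
        ),
        GlycosideSpec(
            "acMedSap",
            "acetylated medicagenic acid",
            {"hexose": 3, "deoxyhexose": 1},
            steps=[{"hexose": 1}, {"deoxyhexose": 1}, {"hexose": 2}],
            rates=[0.09, 0.10, 0.12],
            base_intensity=3e6,
            rt_start_min=14.5,
            rt_step_min=1.5,
        ),
        GlycosideSpec(
            "isoquercetin",
            "quercetin",
            {"hexose": 1},
            steps=[{"hexose": 1}],
            rates=[0.10],
            base_intensity=2e6,
            rt_start_min=11.7,
            rt_step_min=4.9,
        ),
    ]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters of the simulated experiment."""

    n_matrix_features: int = 488
    n_replicates: int = 3
    colon_times_h: Tuple[float, ...] = COLON_TIMES_H
    noise_cv: float = 0.20
    detection_floor: float = 1e3
    isotopologue: bool = True
    precolon_decay: float = 0.10  # total fractional loss across S and SI, both arms
    matrix_intensity_range: Tuple[float, float] = (5e3, 5e6)
    mz_range: Tuple[float, float] = (150.0, 1800.0)
    rt_range_min: Tuple[float, float] = (0.5, 28.0)
    ms2_coverage: float = 0.8
    ppm_jitter: float = 2.0
    seed: int = 0


def _chain_intensities(rates: Sequence[float], i0: float, times: np.ndarray) -> np.ndarray:
    """Species x time matrix for a linear first-order chain starting at i0.

    The terminal species does not decay.  Solved with the matrix
    exponential, exact to machine precision for the closed-form cases.
    """
    n = len(rates) + 1
    A = np.zeros((n, n))
    for k, r in enumerate(rates):
        A[k, k] -= r
        A[k + 1, k] += r
    out = np.empty((n, len(times)))
    x0 = np.zeros(n)
    x0[0] = i0
    for j, t in enumerate(times):
        out[:, j] = expm(A * t) @ x0
    return out


def _sample_index(config: GeneratorConfig) -> pd.DataFrame:
    rows = []
    phases = [("T0", PRECOLON_TIMES_H["T0"]), ("S", PRECOLON_TIMES_H["S"]),
              ("SI", PRECOLON_TIMES_H["SI"])] + [("COLON", t) for t in config.colon_times_h]
    for cls in CLASSES:
        for phase, t in phases:
            for rep in range(1, config.n_replicates + 1):
                label = f"{cls}_{phase}{'' if phase != 'COLON' else int(t)}_r{rep}"
                rows.append((label, cls, phase, t, rep))
    return pd.DataFrame(
        rows, columns=["sample", "class_", "phase", "time_h", "replicate"]
    ).set_index("sample")


def simulate_gi_experiment(
    config: GeneratorConfig = GeneratorConfig(),
    glycosides: Optional[Sequence[GlycosideSpec]] = None,
    seed: Optional[int] = None,
) -> Tuple[FeatureTable, Dict[str, object]]:
    """Simulate the three-arm longitudinal feature table with ground truth.

    Returns ``(table, truth)`` where ``truth`` carries a per-feature frame
    (species, family, chain step, true role, carbon count, isotope
    parentage) and the list of true residue-labelled biotransformation
    edges.  Fixed seed implies bit-identical output.
    """
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    specs = list(default_glycoside_library() if glycosides is None else glycosides)

    samples = _sample_index(config)
    colon_t = np.asarray(config.colon_times_h, dtype=float)

    feat_rows: List[Dict[str, object]] = []
    clean: List[np.ndarray] = []  # noise-free per-sample values
    truth_rows: List[Dict[str, object]] = []
    true_edges: List[Tuple[str, str, Dict[str, int]]] = []

    d = config.precolon_decay
    pre_level = {"T0": 1.0, "S": 1.0 - d / 2, "SI": 1.0 - d}

    cls_arr = samples["class_"].to_numpy()
    phase_arr = samples["phase"].to_numpy()
    time_arr = samples["time_h"].to_numpy(dtype=float)
    is_colon = phase_arr == "COLON"
    colon_idx = np.where(is_colon, np.searchsorted(colon_t, time_arr), 0)

    def sample_values(hex_colon: np.ndarray, pre: Mapping[str, float],
                      nchex_colon: float, mb_colon: float) -> np.ndarray:
        pre_vals = np.array([pre.get(ph, 0.0) for ph in phase_arr])
        vals = pre_vals.copy()
        vals[is_colon & (cls_arr == "HEX")] = hex_colon[colon_idx[is_colon & (cls_arr == "HEX")]]
        vals[is_colon & (cls_arr == "NCHEX")] = nchex_colon
        vals[cls_arr == "MB"] = 0.0
        vals[(cls_arr == "MB") & is_colon] = mb_colon
        return vals

    for spec in specs:
        i0 = spec.base_intensity * (1.0 - d)  # level entering the colon
        chain = _chain_intensities(spec.rates, i0, colon_t)
        n_sp = spec.n_species
        for k in range(n_sp):
            fid = f"{spec.name}/s{k}"
            pre = (
                {ph: spec.base_intensity * lv for ph, lv in pre_level.items()}
                if k == 0
                else {ph: 0.0 for ph in pre_level}
            )
            nchex_level = i0 if k == 0 else 0.0
            vals = sample_values(chain[k], pre, nchex_level, 0.0)
            formula = spec.species_formula(k)
            role = (
                "substrate" if k == 0
                else "product" if k == n_sp - 1
                else "intermediate"
            )
            feat_rows.append(
                {"id": fid, "mz": spec.species_mz(k), "rt_min": spec.species_rt(k),
                 "width_min": 0.2}
            )
            clean.append(vals)
            truth_rows.append(
                {"id": fid, "kind": "extract", "family": spec.name, "step": k,
                 "species": str(formula), "role_truth": role,
                 "c_count": formula["C"], "isotope_of": None}
            )
            if k > 0:
                true_edges.append(
                    (f"{spec.name}/s{k-1}", fid, dict(spec.steps[k - 1]))
                )

    # matrix features: fecal/enzyme background, colon phase of HEX and MB only
    extract_mz = np.array([r["mz"] for r in feat_rows])
    n_matrix = config.n_matrix_features
    matrix_mz: List[float] = []
    while len(matrix_mz) < n_matrix:
        cand = rng.uniform(*config.mz_range)
        near = np.concatenate([extract_mz, np.asarray(matrix_mz, dtype=float)])
        # keep both the peak and its M+1 well clear of every other peak
        if near.size and np.min(np.abs(near[:, None] - (cand + np.array([0.0, ISOTOPE_SPACING, -ISOTOPE_SPACING])[None, :]))) < 0.05:
            continue
        matrix_mz.append(cand)
    for j, mzv in enumerate(matrix_mz):
        fid = f"matrix/{j:04d}"
        level = float(np.exp(rng.uniform(
            np.log(config.matrix_intensity_range[0]),
            np.log(config.matrix_intensity_range[1]),
        )))
        vals = sample_values(
            np.full(len(colon_t), level), {ph: 0.0 for ph in pre_level}, 0.0, level
        )
        feat_rows.append(
            {"id": fid, "mz": mzv, "rt_min": float(rng.uniform(*config.rt_range_min)),
             "width_min": 0.2}
        )
        clean.append(vals)
        truth_rows.append(
            {"id": fid, "kind": "matrix", "family": None, "step": None,
             "species": None, "role_truth": "matrix",
             "c_count": int(round(mzv / 19.0)), "isotope_of": None}
        )

    # multiplicative log-normal noise, then optional isotopologues (which
    # inherit the parent's realised noise so that they co-vary), then floor
    sigma = float(np.sqrt(np.log(1.0 + config.noise_cv ** 2)))
    n_feat = len(feat_rows)
    noisy = np.empty((n_feat, len(samples)))
    for i in range(n_feat):
        z = rng.standard_normal(len(samples))
        noisy[i] = clean[i] * np.exp(sigma * z - sigma ** 2 / 2)

    iso_rows: List[Dict[str, object]] = []
    iso_vals: List[np.ndarray] = []
    if config.isotopologue:
        for i, (fr, tr) in enumerate(zip(list(feat_rows), list(truth_rows))):
            abundance = 0.011 * tr["c_count"]
            # an M+1 whose intensity never clears the detection floor would
            # not be picked as a feature; emit only detectable isotopologues
            if abundance * np.max(clean[i]) < 2.0 * config.detection_floor:
                continue
            jitter = np.exp(0.01 * rng.standard_normal(len(samples)))
            iso = noisy[i] * abundance * jitter
            iso_rows.append(
                {"id": fr["id"] + "+1", "mz": fr["mz"] + ISOTOPE_SPACING,
                 "rt_min": fr["rt_min"], "width_min": fr["width_min"]}
            )
            iso_vals.append(iso)
            truth_rows.append(
                {"id": fr["id"] + "+1", "kind": "isotope", "family": tr["family"],
                 "step": tr["step"], "species": tr["species"],
                 "role_truth": "isotope", "c_count": tr["c_count"],
                 "isotope_of": fr["id"]}
            )
        feat_rows += iso_rows
        noisy = np.vstack([noisy] + [v[None, :] for v in iso_vals]) if iso_vals else noisy

    noisy = np.where(noisy < config.detection_floor, np.nan, noisy)

    features = pd.DataFrame(feat_rows).set_index("id")
    intensities = pd.DataFrame(noisy, index=features.index, columns=samples.index)
    table = FeatureTable(features, intensities, samples)
    truth = {
        "features": pd.DataFrame(truth_rows).set_index("id"),
        "edges": true_edges,
        "specs": specs,
    }
    return table, truth


def simulate_global_null(
    n_features: int = 500,
    config: GeneratorConfig = GeneratorConfig(),
    mean_intensity: float = 1e5,
    seed: int = 0,
) -> FeatureTable:
    """Every arm drawn from one noise model: no class effect anywhere.

    Used to calibrate the differential-profile test's type-I error — under
    this null the fraction of p-values below alpha should be alpha.
    """
    rng = np.random.default_rng(seed)
    samples = _sample_index(config)
    sigma = float(np.sqrt(np.log(1.0 + config.noise_cv ** 2)))
    Y = mean_intensity * np.exp(
        sigma * rng.standard_normal((n_features, len(samples))) - sigma ** 2 / 2
    )
    features = pd.DataFrame(
        {"mz": np.linspace(200.0, 1500.0, n_features), "rt_min": 10.0, "width_min": 0.2},
        index=[f"null/{i:04d}" for i in range(n_features)],
    )
    intensities = pd.DataFrame(Y, index=features.index, columns=samples.index)
    return FeatureTable(features, intensities, samples)


# ---------------------------------------------------------------------------
# MS/MS ladder simulation
# ---------------------------------------------------------------------------

def fragment_ladder(aglycone: str, sugars: Mapping[str, int]) -> Dict[float, str]:
    """Exhaustive negative-mode fragment ladder of a glycoside composition.

    Ions: every sub-multiset loss from the deprotonated precursor
    (equivalently every aglycone-plus-residues ion), the deprotonated
    detached sugar chains, and the aglycone - H2O - CO2 ion.  Keys are
    theoretical m/z, values a tag; the precursor itself is excluded.
    """
    from .glycan import _candidate_interpretations  # shared enumeration
    from .masses import monoisotopic_mass

    agl = AGLYCONES[aglycone]
    precursor_neutral = monoisotopic_mass(agl + residue_multiset_formula(sugars))
    out: Dict[float, str] = {}
    for kind, _losses, mz in _candidate_interpretations(
        dict(sugars), monoisotopic_mass(agl), precursor_neutral, RESIDUES
    ):
        if kind in ("precursor-side loss",) and not _losses:
            continue
        if kind == "aglycone-H2O ion":
            continue  # keep the ladder to the ions the annotation contract names
        if mz > 0:
            out.setdefault(round(mz, 9), kind)
    return out


def simulate_ms2(
    aglycone: str,
    sugars: Mapping[str, int],
    coverage: float = 0.8,
    ppm_jitter: float = 2.0,
    seed: int = 0,
) -> Dict[str, object]:
    """A simulated MS² spectrum of one glycoside composition.

    Each ladder fragment is retained independently with probability
    ``coverage``; every retained m/z (and the always-present precursor) is
    perturbed by Gaussian ppm jitter.  ``coverage=0`` yields a
    precursor-only spectrum.
    """
    if not 0.0 <= coverage <= 1.0:
        raise ValueError("coverage must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    agl = AGLYCONES[aglycone]
    precursor = theoretical_mz(agl + residue_multiset_formula(sugars), "[M-H]-")
    ladder = fragment_ladder(aglycone, sugars)
    frags = [mz for mz in sorted(ladder) if coverage == 1.0 or rng.random() < coverage]

    def jitter(mz: float) -> float:
        if ppm_jitter == 0:
            return mz
        return mz * (1.0 + 1e-6 * ppm_jitter * rng.standard_normal())

    return {
        "precursor_mz": jitter(precursor),
        "fragments": [jitter(m) for m in frags],
        "truth": {"aglycone": aglycone, "sugars": dict(sugars),
                  "ladder": ladder, "precursor_mz": precursor},
    }


# ---------------------------------------------------------------------------
# Hepatic (S9) simulation
# ---------------------------------------------------------------------------

DEFAULT_PLANTED_RULES: Tuple[str, ...] = (
    "hydroxylation",
    "double hydroxylation",
    "oxidation of hydroxy group",
    "hydroxylation+oxidation",
    "glucuronidation",
    "carboxylic acid reduction (aldehyde)",
)


def simulate_s9(
    parent: str | ElementalFormula = "C30H46O6",
    planted_rules: Sequence[str] = DEFAULT_PLANTED_RULES,
    n_matrix: int = 200,
    n_replicates: int = 3,
    noise_cv: float = 0.2,
    metabolite_intensity: float = 1e6,
    parent_intensity: float = 5e6,
    matrix_intensity_range: Tuple[float, float] = (1e4, 1e6),
    mz_range: Tuple[float, float] = (150.0, 900.0),
    seed: int = 0,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Sample and quenched-negative-control intensity tables with truth.

    The parent aglycone and the matrix features appear in both arms;
    rule-derived metabolites appear only in the incubated samples (the
    quenched control never formed them).  Returns
    ``(sample, control, truth)`` where the frames are feature x replicate
    and ``truth`` records each feature's m/z, kind and generating rule.
    """
    if isinstance(parent, str):
        parent = ElementalFormula.parse(parent)
    rng = np.random.default_rng(seed)
    rules = {r.name: r for r in DEFAULT_RULES}

    rows: List[Dict[str, object]] = []
    rows.append({"id": "parent", "mz": theoretical_mz(parent, "[M-H]-"),
                 "kind": "parent", "rule": None,
                 "sample_level": parent_intensity, "control_level": parent_intensity})
    for rname in planted_rules:
        f = rules[rname].apply(parent)
        if f is None:
            raise ValueError(f"rule {rname!r} not applicable to the parent")
        rows.append({"id": f"met/{rname}", "mz": theoretical_mz(f, "[M-H]-"),
                     "kind": "metabolite", "rule": rname,
                     "sample_level": metabolite_intensity, "control_level": 0.0})
    known_mz = np.array([r["mz"] for r in rows])
    while sum(r["kind"] == "matrix" for r in rows) < n_matrix:
        cand = rng.uniform(*mz_range)
        if np.min(np.abs(known_mz - cand)) < 0.05:
            continue
        level = float(np.exp(rng.uniform(
            np.log(matrix_intensity_range[0]), np.log(matrix_intensity_range[1])
        )))
        rows.append({"id": f"mat/{sum(r['kind'] == 'matrix' for r in rows):04d}",
                     "mz": cand, "kind": "matrix", "rule": None,
                     "sample_level": level, "control_level": level})
        known_mz = np.append(known_mz, cand)

    sigma = float(np.sqrt(np.log(1.0 + noise_cv ** 2)))

    def draw(level: float) -> np.ndarray:
        if level <= 0:
            return np.zeros(n_replicates)
        z = rng.standard_normal(n_replicates)
        return level * np.exp(sigma * z - sigma ** 2 / 2)

    ids = [r["id"] for r in rows]
    sample = pd.DataFrame(
        [draw(r["sample_level"]) for r in rows],
        index=ids, columns=[f"S{i+1}" for i in range(n_replicates)],
    )
    control = pd.DataFrame(
        [draw(r["control_level"]) for r in rows],
        index=ids, columns=[f"C{i+1}" for i in range(n_replicates)],
    )
    truth = pd.DataFrame(rows).set_index("id")
    return sample, control, truth
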