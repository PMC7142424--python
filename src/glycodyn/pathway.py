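"""Temporal trend calling and deglycosylation-network inference.

A saponin being deglycosylated by colonic microbiota decays in the
extract+bacteria arm (HEX) but not in the bacteria-free negative control
(NCHEX); each of its partially deglycosylated successors rises and then
falls as the chain passes through it, and the terminal aglycone
accumulates.  ``call_trend`` classifies these behaviours per feature;
``infer_network`` links decreasing precursors to increasing products
whenever the m/z difference decomposes into sugar residues; and
``pathway_report`` reads ordered precursor-to-aglycone chains off the
resulting graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .feature_table import FeatureTable
from .glycan import RESIDUES, ResidueLibrary, decompose_delta, residue_multiset_mass
from .timeseries import _colon_profile

__all__ = [
    "TrendCall",
    "BiotransformationEdge",
    "call_trend",
    "call_trends",
    "infer_network",
    "pathway_report",
]

ROLES = ("substrate", "product", "intermediate", "matrix", "unrelated")
DIRECTIONS = ("increase", "decrease", "flat", "absent")


@dataclass
class TrendCall:
    feature_id: object
    directions: Dict[str, str]  # class -> direction
    role: str


@dataclass
class BiotransformationEdge:
    source: object
    target: object
    losses: Dict[str, int]
    delta_mass: float
    ppm: float
    evidence: float

    def label(self) -> str:
        return " + ".join(f"{n}x {r}" if n > 1 else r for r, n in sorted(self.losses.items()))


def _theil_sen(t: np.ndarray, y: np.ndarray) -> float:
    ok = ~np.isnan(y)
    if ok.sum() < 3 or np.ptp(y[ok]) == 0:
        return 0.0
    return float(stats.theilslopes(y[ok], t[ok])[0])


def _class_direction(
    t: np.ndarray,
    prof: np.ndarray,
    detection: float,
    slope_threshold: float,
    net_delta: float = 0.5,
) -> Tuple[str, np.ndarray]:
    """Direction of one class's colon profile; returns (direction, log profile).

    A direction is called from the robust slope, or — for saturating
    profiles whose median pairwise slope flattens out — from a net
    first-to-last change of at least ``net_delta`` log units.
    """
    detected = np.where((np.isnan(prof)) | (prof < detection), np.nan, prof)
    logp = np.log(detected + 1.0)
    if np.all(np.isnan(logp)):
        return "absent", logp
    slope = _theil_sen(t, logp)
    if slope > slope_threshold:
        return "increase", logp
    if slope < -slope_threshold:
        return "decrease", logp
    ok = np.flatnonzero(~np.isnan(logp))
    net = logp[ok[-1]] - logp[ok[0]] if ok.size >= 2 else 0.0
    if net >= net_delta:
        return "increase", logp
    if net <= -net_delta:
        return "decrease", logp
    return "flat", logp


def _rise_and_fall(t: np.ndarray, logp: np.ndarray, delta: float) -> bool:
    """True when the profile climbs by >= delta log-units to an interior peak
    and falls by >= delta afterwards (the intermediate signature)."""
    ok = ~np.isnan(logp)
    if ok.sum() < 4:
        return False
    tt, yy = t[ok], logp[ok]
    k = int(np.argmax(yy))
    if k == 0 or k == len(yy) - 1:
        return False
    rise = yy[k] - yy[0]
    fall = yy[k] - yy[-1]
    return rise >= delta and fall >= delta


def call_trend(
    table: FeatureTable,
    fid,
    slope_threshold: float = 0.05,
    detection_fraction: float = 0.01,
    peak_delta: float = 0.5,
) -> TrendCall:
    """Per-class colon-phase direction and biotransformation role of a feature.

    Directions come from robust (Theil-Sen) slopes of log intensity over
    colon time; values below ``detection_fraction`` of the feature's own
    maximum count as absent (scale-free detection limit).  Roles:

    - ``matrix``: present in the method blank (MB);
    - ``intermediate``: HEX rises and falls around an interior peak
      (>= ``peak_delta`` log units each way) while NCHEX does not decrease;
    - ``substrate``: HEX decreases while NCHEX does not;
    - ``product``: HEX increases while NCHEX does not;
    - ``unrelated`` otherwise.
    """
    x = table.intensities.loc[fid].to_numpy(dtype=float)
    xmax = np.nanmax(np.where(np.isnan(x), 0.0, x)) if len(x) else 0.0
    detection = detection_fraction * xmax if xmax > 0 else np.inf

    directions: Dict[str, str] = {}
    logs: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for cls in ("HEX", "NCHEX", "MB"):
        t, prof = _colon_profile(table, fid, cls)
        d, logp = _class_direction(t, prof, detection, slope_threshold)
        directions[cls] = d
        logs[cls] = (t, logp)

    if directions["MB"] != "absent":
        role = "matrix"
    elif directions["HEX"] == "absent":
        role = "unrelated"
    elif (
        _rise_and_fall(*logs["HEX"], peak_delta)
        and directions["NCHEX"] != "decrease"
    ):
        role = "intermediate"
    elif directions["HEX"] == "decrease" and directions["NCHEX"] != "decrease":
        role = "substrate"
    elif directions["HEX"] == "increase" and directions["NCHEX"] != "increase":
        role = "product"
    else:
        role = "unrelated"
    return TrendCall(fid, directions, role)


def call_trends(table: FeatureTable, **kw) -> Dict[object, TrendCall]:
    return {fid: call_trend(table, fid, **kw) for fid in table.features.index}


def _lagged_negative_correlation(
    t: np.ndarray, src: np.ndarray, tgt: np.ndarray, max_lag: int = 2
) -> float:
    """max over lags 0..max_lag of -corr(src[:-lag], tgt[lag:]), clipped at 0.

    A product's rise trails its precursor's fall, so the anticorrelation is
    strongest at a small positive lag of the product profile.
    """
    best = 0.0
    s = np.nan_to_num(src)
    g = np.nan_to_num(tgt)
    for lag in range(0, max_lag + 1):
        a = s[: len(s) - lag] if lag else s
        b = g[lag:] if lag else g
        if len(a) < 3 or np.ptp(a) == 0 or np.ptp(b) == 0:
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        best = max(best, -r)
    return best


def infer_network(
    trends: Mapping[object, TrendCall],
    table: FeatureTable,
    residues: ResidueLibrary | None = None,
    tol_ppm: float = 5.0,
    require_complementary: bool = True,
    max_residues: int = 3,
    transitive_reduction: bool = True,
) -> List[BiotransformationEdge]:
    """Residue-labelled precursor-to-product edges.

    For every ordered feature pair with a positive m/z difference that
    decomposes into at most ``max_residues`` sugar residues (same-adduct
    assumption, tolerance ``tol_ppm`` of the precursor m/z), and — when
    ``require_complementary`` — with source role in {substrate,
    intermediate} and target role in {intermediate, product}, an edge is
    emitted carrying the best decomposition.  The evidence score combines
    the relative mass error with the lagged anticorrelation of the HEX colon
    profiles.  With ``transitive_reduction`` (default), an edge whose loss
    equals the summed losses along an existing two-step path between the
    same nodes is removed: stepwise elimination is the parsimonious reading
    of a ladder.
    """
    lib = residues or RESIDUES
    feats = table.features
    mz = feats["mz"]

    sources = [
        f for f, tr in trends.items()
        if not require_complementary or tr.role in ("substrate", "intermediate")
    ]
    targets = [
        f for f, tr in trends.items()
        if not require_complementary or tr.role in ("intermediate", "product")
    ]

    profiles = {}

    def hex_profile(fid):
        if fid not in profiles:
            t, prof = _colon_profile(table, fid, "HEX")
            profiles[fid] = (t, np.log(np.nan_to_num(prof) + 1.0))
        return profiles[fid]

    edges: List[BiotransformationEdge] = []
    for s in sources:
        for g in targets:
            if s == g:
                continue
            delta = float(mz[s] - mz[g])
            if delta <= 0:
                continue
            tol_da = tol_ppm * 1e-6 * float(mz[s])
            decomps = decompose_delta(
                delta, lib, tol=tol_da, max_count=max_residues,
                tol_unit="Da", max_total=max_residues,
            )
            decomps = [(m, e) for m, e in decomps if m]
            if not decomps:
                continue
            losses, err = decomps[0]
            t, ps = hex_profile(s)
            _, pg = hex_profile(g)
            comp = _lagged_negative_correlation(t, ps, pg)
            evidence = 0.5 * (1.0 - abs(err) / tol_da) + 0.5 * comp
            edges.append(
                BiotransformationEdge(
                    s, g, losses, delta, err / float(mz[s]) * 1e6 * -1.0, evidence
                )
            )

    if transitive_reduction:
        edges = _reduce_transitive(edges)
    edges.sort(key=lambda e: (-e.evidence, str(e.source), str(e.target)))
    return edges


def _reduce_transitive(edges: List[BiotransformationEdge]) -> List[BiotransformationEdge]:
    by_src: Dict[object, List[BiotransformationEdge]] = {}
    for e in edges:
        by_src.setdefault(e.source, []).append(e)
    pairs = {(e.source, e.target): e for e in edges}

    def losses_sum(a: Mapping[str, int], b: Mapping[str, int]) -> Dict[str, int]:
        out = dict(a)
        for k, v in b.items():
            out[k] = out.get(k, 0) + v
        return out

    drop = set()
    for e in edges:
        for mid_edge in by_src.get(e.source, []):
            follow = pairs.get((mid_edge.target, e.target))
            if follow is None or mid_edge is e:
                continue
            if losses_sum(mid_edge.losses, follow.losses) == e.losses:
                drop.add((e.source, e.target))
                break
    return [e for e in edges if (e.source, e.target) not in drop]


def pathway_report(
    edges: Sequence[BiotransformationEdge],
    annotations: Optional[Mapping[object, str]] = None,
) -> Dict[str, object]:
    """Ordered deglycosylation chains from largest precursor to aglycone.

    Decomposes the edge graph into maximal source-to-sink paths.  Cycles are
    reported under ``"cycles"`` as anomalies, never silently broken; the
    chain decomposition covers the acyclic part.
    """
    g = nx.DiGraph()
    for e in edges:
        g.add_edge(e.source, e.target, losses=e.losses, evidence=e.evidence)

    cycles = list(nx.simple_cycles(g))
    dag = g.copy()
    for cyc in cycles:
        for a, b in zip(cyc, cyc[1:] + cyc[:1]):
            if dag.has_edge(a, b):
                dag.remove_edge(a, b)

    roots = [n for n in dag.nodes if dag.in_degree(n) == 0 and dag.out_degree(n) > 0]
    leaves = {n for n in dag.nodes if dag.out_degree(n) == 0}
    chains: List[List[object]] = []
    for r in sorted(roots, key=str):
        for leaf in sorted(leaves, key=str):
            for path in nx.all_simple_paths(dag, r, leaf):
                chains.append(path)
    # keep maximal chains only (drop strict sub-chains)
    as_tuples = [tuple(c) for c in chains]
    maximal = [
        list(c) for c in as_tuples
        if not any(c != o and _is_subpath(c, o) for o in as_tuples)
    ]
    report = {
        "chains": maximal,
        "cycles": cycles,
        "n_edges": len(edges),
    }
    if annotations:
        report["labels"] = {
            n: annotations.get(n, "") for chain in maximal for n in chain
        }
    return report


def _is_subpath(short: Tuple, long: Tuple) -> bool:
    if len(short) > len(long):
        return False
    return any(long[i : i + len(short)] == short for i in range(len(long) - len(short) + 1))
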