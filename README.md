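# glycodyn

Dynamic-metabolomics analysis of glycoside biotransformation: who loses
which sugar, when, and what the liver does to the aglycone afterwards.

Herbal extracts rich in saponins and flavonoid glycosides are transformed
by gut microbiota: glycosidic bonds are hydrolysed stepwise until the
aglycone remains, and the aglycone is then further metabolised by hepatic
phase I/II enzymes. `glycodyn` implements the computational side of an in
vitro study of this process end to end:

- **Accurate-mass arithmetic** (`glycodyn.masses`) — monoisotopic masses,
  an adduct dialect covering `[M-H]-`, `[M+Na]+`, `[M-2H]2-`, formate and
  sodium-formate adducts and multimers, signed ppm deviations, and
  exhaustive brute-force enumeration of C/H/O formulas inside a ppm window.
  For an ion at m/z `mz_obs` and a candidate neutral formula F,
  `ppm = (mz_obs − mz(F)) / mz(F) × 1e6` with `mz(F) = M(F) − m_p` in
  negative mode (electron mass accounted for).
- **Glycan annotation** (`glycodyn.glycan`) — decomposition of mass
  differences into glycosyl-residue multisets (pentosyl 132.0423,
  deoxyhexosyl 146.0579, hexosyl 162.0528, uronic acid 176.0321 Da; bounded
  knapsack, exhaustive) and ranking of aglycone + sugar-composition
  annotations for MS/MS spectra, with per-fragment loss-chain explanations.
- **Longitudinal feature processing** (`glycodyn.timeseries`) — peak-width
  filtering, isotopologue flagging (spacing 1.003355/z Da, co-elution,
  intensity correlation), a spline-based permutation F-test for
  class-dependent time profiles across the three study arms (extract +
  bacteria, extract without bacteria, blank), profile descriptors, a
  random-forest "interestingness" scorer trained on expert ratings, and
  candidate selection (score > 0.8, retention time 2–25 min).
- **Pathway inference** (`glycodyn.pathway`) — robust trend calling per arm
  (substrate / intermediate / product / matrix) and residue-labelled
  deglycosylation networks linking decreasing precursors to increasing
  products, read out as ordered precursor-to-aglycone chains.
- **Hepatic screen** (`glycodyn.hepatic`) — breadth-first phase I/II
  suspect-mass prediction from elemental-composition rules (hydroxylation,
  oxidation, carboxylic-acid reduction, glucuronidation, sulfation,
  acetylation, glutathione conjugation; depth ≤ 3, ≤ 1000 products) plus a
  volcano screen (fold change + two-sample t-test) against quenched
  negative controls, with unmatched candidates kept as nontarget hits.
- **Synthetic data** (`glycodyn.synthetic`) — a ground-truthed generator of
  the whole study design: three arms, T0/gastric/small-intestinal time
  points and a 2–72 h colonic grid, sequential first-order deglycosylation
  kinetics (dI_k/dt = k_{k−1} I_{k−1} − k_k I_k), matrix features, M+1
  isotopologues, multiplicative log-normal noise and a detection floor;
  plus MS² fragment-ladder and hepatic S9 sample/control simulators.

## Worked example

The flagship identification: a bidesmosidic saponin at m/z 1703.71838
(`[M-H]-`) with five product ions.

```python
from glycodyn import annotate_glycoside

frags = [1381.62830, 879.30701, 823.41089, 501.32275, 439.31934]
top = annotate_glycoside(1703.71838, "[M-H]-", frags)[0]
print(top.describe())
```

prints

```
medicagenic acid + 3x deoxyhexose + 2x hexose + 2x pentose + uronic acid  (precursor 1703.71838, +0.14 ppm)
  1381.62830  precursor-side loss [deoxyhexose + uronic acid]  (+0.11 ppm)
  879.30701  sugar-chain ion [2x deoxyhexose + 2x hexose + 2x pentose]  (+9.44 ppm)
  823.41089  aglycone+residues ion [deoxyhexose + uronic acid]  (-1.54 ppm)
  501.32275  aglycone ion [3x deoxyhexose + 2x hexose + 2x pentose + uronic acid]  (+1.17 ppm)
  439.31934  aglycone-H2O-CO2 ion [CO2 + water]  (-5.53 ppm)
```

Read: the precursor matches medicagenic acid carrying three deoxyhexosyl,
two hexosyl, two pentosyl and one uronic-acid residue to +0.14 ppm. The
ion at 1381.6 is the precursor after losing a uronic acid and a
deoxyhexose; 879.3 is a detached six-residue sugar chain; 823.4 is the
aglycone still carrying a deoxyhexose and the uronic acid; 501.3 is the
deprotonated aglycone itself and 439.3 its water/CO₂ loss.

A full simulated study runs from the command line:

```sh
glycodyn simulate gi --out sim --seed 1
glycodyn pipeline --features sim/features.csv --samples sim/samples.csv --out run --seed 1
```

`run/edges.tsv` then contains the recovered deglycosylation network (e.g.
`hernH/s0 → hernH/s1  hexose`), and `run/pathways.json` the ordered chains
ending at the aglycones.

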