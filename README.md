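# lctrace

Stable-isotope tracer metabolomics, end to end: find labeled metabolites in
LC-MS data, quantify how fast the label is incorporated, and relate tissue
and urine compartments — with a synthetic-data generator that makes every
stage testable against known ground truth.

The package targets the analysis behind in-vivo lysine tracing: animals fed
¹³C₆-lysine (or given a ¹⁵N-lysine bolus) accumulate label in lysine,
its degradation products (saccharopine, pipecolic acid, aminoadipic acid),
modified lysines (acetyl-, malonyl-, fructosyl-lysine), carnitine-pathway
products and peptides. Two complementary detectors find these species:

1. **Untargeted mass-difference detection** (`lctrace.envelopes`): group
   aligned features into light/heavy envelopes when a partner sits at an
   exact tracer shift (+6×1.003355 Da for ¹³C₆, +4 for ¹³C₄,
   +0.997035 Da for ¹⁵N₁) within 10 ppm and 2 s RT, then keep envelopes
   whose heavy member is significantly higher in labeled samples
   (Welch t on log₁₀, fold change ≥ 1.5, p < 0.05, BH q < 0.05).
2. **Targeted correlation screening** (`lctrace.targeted`): per target
   compound, extract a ±10 ppm EIC from the raw centroided run, smooth it
   (Savitzky–Golay, window 9 / order 3), gate on 1000 counts and S/N ≥ 3,
   and confirm each isotopologue by Pearson correlation ≥ 0.9 with the
   monoisotopic trace over the shared peak window.

Downstream, `lctrace.kinetics` converts isotopologue intensities into
natural-abundance-corrected heavy/light ratios `r_corr = I_k/I_0 −
n·a_h/a_l`, fits the incorporation slope by OLS over the first two weeks,
and summarizes by compound class; `lctrace.integrate` handles creatinine
normalization, differential filtering and cross-compartment correlation
networks. `lctrace.chem` provides the mass basis (monoisotopic masses,
adduct m/z, MRM transition pairs), and `lctrace.simulate` generates
feature tables and raw mzML runs with mono-exponential enrichment
f(t) = 0.95·(1 − e^(−k t)) and per-class rate constants.

## Worked example

```python
from lctrace.chem import parse_formula, monoisotopic_mass, adduct_mz, heavy_transition

neutral = monoisotopic_mass(parse_formula("C9H16N2O5"))   # malonyl-lysine
print(round(adduct_mz(neutral, "M+H"), 2))    # 233.11
print(round(adduct_mz(neutral, "M+Na"), 2))   # 255.1
print(heavy_transition(233.1132, 84.0808, 6, 5, "13C"))   # (239, 89)
```

The protonated and sodiated ions of Nε-malonyl-lysine come out at 233.11
and 255.10, and six ¹³C labels (five retained in the 84 immonium-type
fragment) shift the nominal MRM transition from 233 → 84 to 239 → 89.

Running the pipeline on synthetic data:

```bash
python analysis/01_simulate.py          # feature table + raw run + truth
python analysis/02_detect_untargeted.py
python analysis/03_screen_targeted.py
python analysis/04_kinetics.py
python analysis/05_integrate.py
```

`02` reports `recovered 10/10 labeled compounds` with `decoys retained:
0/5`; `03` confirms the tracer channel for all ten targets (correlations
≈ 0.99) and full overlap with the untargeted route; `04` prints per-class
incorporation slopes that recover the generator's rate ordering (lysine
fastest, acylcarnitines slowest, four-carbon backbones slower than
six-carbon); `05` retains the planted positive cortex-lysine/urine-lysine
edge and prints the planted negative albumin edge with its q-value.

The same stages are available as a CLI (`lctrace simulate`,
`lctrace detect-untargeted`, `lctrace screen-targeted`, `lctrace
kinetics`, `lctrace integrate`), each driven by a YAML config plus a seed
and writing a JSON manifest beside its outputs.

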