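# Methods

`lctrace` implements the computational core of an in-vivo stable-isotope
tracer metabolomics study: animals receive ¹³C₆-lysine through the diet (or a
¹⁵N-lysine bolus), and LC-MS data from their tissues and fluids are mined for
labeled metabolites, incorporation kinetics, and integrative tissue/fluid
relationships. Everything runs against a synthetic-data generator with known
ground truth, so each stage is testable without the animal data.

## Mass basis

All m/z arithmetic rests on a pinned table of NIST monoisotopic atomic
masses and IUPAC terrestrial abundances (`constants.py`). Pinning the table
inside the package makes printed m/z values bit-stable. Adduct mass deltas
include the electron mass: at two decimals this is invisible (the worked
values 233.11 / 255.10 for protonated and sodiated Nε-malonyl-lysine,
C₉H₁₆N₂O₅, are insensitive), but at the fourth decimal it matters for
10 ppm matching. Only singly charged species are supported; everything the
pipeline targets ionizes singly, and multiply charged input is rejected
rather than silently divided.

Tracer shifts are per-atom heavy-minus-light mass differences:
1.0033548 Da per ¹³C and 0.9970349 Da per ¹⁵N. Nominal (unit-resolution,
triple-quadrupole) m/z is round-half-away-from-zero of the exact value,
which reproduces printed integer MRM transitions such as the 233 → 239
precursor shift of ¹³C₆ malonyl-lysine and its fragment pairs
(84 → 89 with five labels retained, 147 → 153 with six). One known
rounding oddity: the exact light fragment 147.1128 rounds to 147.11, while
targeted assay tables sometimes quote 147.10; the package always reports
exact values and rounds only at presentation.

The natural-abundance term uses the linear single-substitution
approximation: n_atoms × a(heavy)/a(light) of the labelable element
(0.010816 per carbon, 0.0036533 per nitrogen). This is accurate to well
under 1% of the term itself for the small formulas involved and is the
term subtracted by the ratio correction (below).

## Synthetic data

The generator defines the study conditions:

- **Design**: time points 0/1/2/8 weeks, three replicates per point,
  time-0 animals double as the unlabeled control group.
- **Enrichment law**: labeled fraction f(t) = plateau·(1 − e^(−k·t)) with
  plateau 0.95 (near-complete labeling after two months on diet). The law
  itself is a modelling choice — the downstream kinetics stage must
  recover its consequences, never assume them.
- **Class rates** (per week): lysine 1.6 > degradation 1.0 > modified 0.8
  > carnitine-pathway 0.45 > peptide 0.28 > acylcarnitine 0.18. The
  ordering encodes the biology to be recovered: free lysine pools turn
  over fastest; proteins and acylcarnitines lag. Compounds inheriting
  only four backbone carbons are modelled as a distinct label count with
  their slower class rate.
- **Isotopologue pattern**: a two-species mixture. The unlabeled species
  splits its signal between the monoisotopic channel and a +1
  natural-abundance satellite; the labeled species carries the full
  backbone label in the top channel. The pattern sums to exactly one, so
  label moves signal between channels without creating it (total ion
  current is conserved at zero noise).
- **Noise**: multiplicative lognormal with mean exactly 1 and configurable
  CV (default 0.1) on feature intensities; raw runs add ±3 ppm uniform
  instrument jitter, a sparse exponential baseline, and Gaussian
  chromatographic peaks (σ 2–4 s, 0.5 s scans). Centroids below one count
  are dropped, and features that are zero in every sample are not emitted
  (a peak picker would not report them).
- **Decoys**: unlabeled compounds whose feature pairs sit at exactly one
  of the expected tracer shifts with group-independent intensities, so
  decoy rejection exercises the statistics, not just the m/z matching.

Every generator is a pure function of (parameters, seed). What the
generator does **not** emulate: ion suppression, chimeric spectra,
retention-time drift across runs, profile-mode peak shape, missing-value
structure from peak-picking failures, and organ-specific kinetics beyond
class-rate multipliers. Passing tests therefore demonstrate correctness of
the algorithms under a clean, well-specified noise model — not performance
on real cohorts.

## Untargeted envelope detection

Features are grouped into candidate envelopes per expected shift (¹³C₆,
¹³C₄, ¹⁵N₁ by default): partners must lie above the base m/z at the exact
shift within 10 ppm (relative to the base) and within 2 s of the base
feature's retention time. The RT window anchors on the base feature
rather than chaining transitively, so envelopes cannot drift. Among
multiple in-tolerance candidates the smallest |ppm error| wins, greedily,
and each feature serves at most once as a partner and once as a base per
shift; sorting features canonically first makes grouping independent of
input order. The greedy matcher is verified against an exhaustive O(n²)
pair-enumeration oracle in the tests.

Heavy partners are then tested labeled-vs-unlabeled with Welch's t-test
on log10 intensities (variance stabilization; two-sided p with direction
carried by the fold change). Zero or missing intensities are floored at
1 count before fold-change and log, and flagged. Benjamini–Hochberg runs
over the family of all tested partners in the run; an envelope is
retained iff at least one partner has fold change ≥ 1.5 in the labeled
direction, p < 0.05 and q < 0.05.

## Targeted correlation screen

Per compound × adduct, an EIC is the per-scan sum of centroids within
±10 ppm of the target m/z. Traces are smoothed with a Savitzky–Golay
filter (window 9 points, order 3 — small enough to preserve 4–8-scan-σ
peaks, large enough to suppress scan-level noise; negative outputs are
clipped to zero). The base (label 0) trace must show a peak: apex = global
maximum, gated at 1000 counts absolute intensity and S/N ≥ 3, where the
noise scale is the robust 1.4826×MAD of the trace outside the peak's
integration bounds (walk-out to 5% of apex height). A flat all-zero
baseline yields infinite S/N — any real peak passes.

Isotopologue channels 1..max are then required to peak within 2 s of the
base apex and to correlate: Pearson r over the union of the two peak
windows (not the full gradient, which would let shared baseline drive
spurious correlation), confirmed at r ≥ 0.9. Pearson makes confirmation
invariant to positive affine scaling of either trace. A confirmed +1
channel is ordinary natural abundance and is reported as such; *tracer*
evidence requires confirmation at the compound's full backbone label
count, and only that counts toward labeled-compound recovery.

## Kinetics

The leading heavy/light ratio is intensity(label k)/intensity(0).
Natural-abundance correction subtracts the single-channel term
n·a(heavy)/a(light) and floors at zero with a flag — full matrix
deconvolution is unnecessary here because the tracer channels (+6, +4,
+1 at high resolution) do not overlap the natural envelope appreciably;
the subtraction is noted as extensible. Incorporation slopes are ordinary
least squares of corrected ratio on time over the early window t ∈ [0, 2]
weeks (t = 0 included), requiring ≥3 points at ≥2 distinct times; for
three equally spaced time points the OLS slope equals the chord slope of
the saturating curve exactly. Class summaries report both summed slopes
(the flow-diagram statistic) and means with SD and n, because sums are
sensitive to class size. Log maximum-isotopologue ratios are log10 of the
top label channel, labeled over unlabeled control, floored at 1 count;
both-zero cases are NaN-flagged and excluded from summaries.

## Integrative statistics

Creatinine normalization divides analyte by creatinine per sample; being
homogeneous of degree +1/−1 it cancels urine volume, which is what makes
stoichiometry comparable across diuresis states. The differential filter
applies Welch (or paired, for before/after designs) t-tests on log10
values with the same FC ≥ 1.5 / p < 0.05 / BH q < 0.05 gate, family =
all metabolites in the matrix. Cross-compartment edges are Pearson
correlations on log10 values across animals (per-animal means when
replicates exist; Spearman switchable), BH-corrected over all
tissue × fluid pairs, retained at q ≤ 0.05 and partitioned by sign;
class-level aggregation counts retained edges per class pair — a
countable statistic suitable for chord rendering. At least four linked
animals are required; below that a correlation is meaningless.

## Determinism, sizes and limits

One global seed fans out to per-stage child seeds through
`numpy.random.SeedSequence`, and every stage writes a manifest (config
hash, seed, version, outputs); deterministic stages reproduce
byte-identical outputs. The bundled study sizes — ten compounds, five
decoys, three replicates × four time points, 8-animal compartment panels,
20–50 seed Monte-Carlo suites — are chosen so the whole analysis runs in
seconds while leaving the statistics enough power to be meaningful; they
are the package's reference conditions, not limits of the methods.

Known limitations: single-charge chemistry only; no peak
picking/alignment (the feature table is consumed as produced by upstream
tools); no MS2 identification; the natural-abundance correction is
single-channel; mzML support covers centroided MS1 with base64 float
arrays (64/32-bit, optional zlib) rather than the full standard.
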