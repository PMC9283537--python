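"""Synthetic stable-isotope labeling experiments with known ground truth.

Emulates the two in-vivo designs the pipeline targets: a dietary 13C6-lysine
time course (0/1/2/8 weeks, triplicates, unlabeled time-0 controls) and a
15N-lysine bolus design, at the level of (a) aligned feature tables as an
XCMS-style peak picker would emit them and (b) raw centroided MS1 runs with
Gaussian chromatographic peaks.

Enrichment follows a mono-exponential rise to a plateau (default 0.95,
matching near-complete lysine labeling after two months on diet) with a
per-compound-class rate constant: free lysine turns over fastest, followed
by degradation products and modified lysines, with carnitine-pathway
products, peptides and acylcarnitines progressively slower. Compounds that
inherit only part of the lysine backbone (13C4 species) are modelled as a
distinct label count with a slower class rate.

Intensities carry multiplicative lognormal noise (mean exactly 1, CV as
configured); raw runs additionally carry +-3 ppm uniform m/z jitter and a
sparse baseline of random noise centroids. Every generator is a pure
function of its parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import (
    ADDUCTS,
    CompoundSpec,
    adduct_mz,
    isotopologue_mz_series,
    natural_isotope_fraction,
    parse_formula,
)
from .constants import ISOTOPE_MASS_SHIFT
from .io import RawRun, Scan

__all__ = [
    "StudyDesign",
    "EnrichmentModel",
    "PeakModel",
    "SimulatedExperiment",
    "DEFAULT_CLASS_RATES",
    "default_panel",
    "simulate_enrichment",
    "isotopologue_pattern",
    "generate_feature_table",
    "generate_label_distributions",
    "generate_raw_run",
    "simulate_eic_pair",
    "generate_compartment_panel",
    "lognormal_noise",
]


# --------------------------------------------------------------- models

@dataclass(frozen=True)
class StudyDesign:
    """Labeling time course: which weeks, how many animals, which organs."""

    time_points: tuple[float, ...] = (0.0, 1.0, 2.0, 8.0)
    replicates_per_point: int = 3
    organs: tuple[str, ...] = ("cortex",)
    seed: int = 0

    def __post_init__(self) -> None:
        if 0.0 not in self.time_points:
            raise ValueError("time 0 (unlabeled control) must be present")
        if self.replicates_per_point < 2:
            raise ValueError("need >=2 replicates per time point")

    def samples(self) -> pd.DataFrame:
        rows = []
        for organ in self.organs:
            for t in self.time_points:
                for r in range(1, self.replicates_per_point + 1):
                    prefix = f"{organ}_" if len(self.organs) > 1 else ""
                    rows.append({
                        "sample_id": f"{prefix}t{t:g}_r{r}",
                        "group": "unlabeled" if t == 0 else "labeled",
                        "time_weeks": t,
                        "compartment": organ,
                        "replicate": r,
                    })
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class EnrichmentModel:
    """Mono-exponential labeled fraction: plateau * (1 - exp(-rate * t))."""

    rate: float           # per week
    plateau: float = 0.95

    def __post_init__(self) -> None:
        if not (0.0 <= self.plateau <= 1.0):
            raise ValueError("plateau must lie in [0, 1]")
        if self.rate < 0:
            raise ValueError("rate must be >= 0")


def simulate_enrichment(t: float, model: EnrichmentModel) -> float:
    """Labeled fraction at time ``t`` weeks; 0 at t=0, bounded by plateau."""
    if t < 0:
        raise ValueError("time must be >= 0")
    return model.plateau * (1.0 - math.exp(-model.rate * t))


# Per-class enrichment rate constants (per week). The ordering encodes the
# biology the pipeline must recover: free lysine exchanges fastest; the
# carnitine pathway, peptide-bound lysine and acylcarnitines lag behind.
DEFAULT_CLASS_RATES: dict[str, float] = {
    "lysine": 1.6,
    "degradation": 1.0,
    "modified": 0.8,
    "carnitine-pathway": 0.45,
    "peptide": 0.28,
    "acylcarnitine": 0.18,
    "other": 0.6,
}


@dataclass(frozen=True)
class PeakModel:
    """Gaussian chromatographic peak: area = height * sigma * sqrt(2*pi)."""

    rt_center: float      # seconds
    rt_sigma: float       # seconds
    height: float         # counts at apex
    scan_interval: float = 0.5

    def __post_init__(self) -> None:
        if self.height <= 0 or self.rt_sigma <= 0 or self.scan_interval <= 0:
            raise ValueError("height, rt_sigma and scan_interval must be > 0")

    def profile(self, times: np.ndarray) -> np.ndarray:
        z = (times - self.rt_center) / self.rt_sigma
        return self.height * np.exp(-0.5 * z * z)


# --------------------------------------------------------- compound panel

def default_panel() -> list[CompoundSpec]:
    """A representative lysine-metabolite panel spanning the class vocabulary."""
    def c(id_, name, formula, labelable, cls):
        return CompoundSpec(id=id_, name=name, formula=parse_formula(formula),
                            labelable=labelable, adducts=("M+H",),
                            compound_class=cls)

    return [
        c("lys", "lysine", "C6H14N2O2", {"13C": 6, "15N": 1}, "lysine"),
        c("sacc", "saccharopine", "C11H20N2O6", {"13C": 6}, "degradation"),
        c("pip", "pipecolic acid", "C6H11NO2", {"13C": 6}, "degradation"),
        c("aaa", "aminoadipic acid", "C6H11NO4", {"13C": 4}, "degradation"),
        c("aclys", "N6-acetyllysine", "C8H16N2O3", {"13C": 6, "15N": 1},
          "modified"),
        c("mallys", "N6-malonyllysine", "C9H16N2O5", {"13C": 6}, "modified"),
        c("fruclys", "fructoselysine", "C12H24N2O7", {"13C": 6}, "modified"),
        c("tml", "trimethyllysine", "C9H20N2O2", {"13C": 6},
          "carnitine-pathway"),
        c("carn", "carnitine", "C7H15NO3", {"13C": 4}, "carnitine-pathway"),
        c("acarn", "acetylcarnitine", "C9H17NO4", {"13C": 4}, "acylcarnitine"),
    ]


# -------------------------------------------------- isotopologue patterns

def isotopologue_pattern(
    c: CompoundSpec, isotope: str, labeled_fraction: float
) -> np.ndarray:
    """Fractional intensity per label count 0..max; sums to exactly 1.

    The unlabeled species contributes its monoisotopic channel plus the
    single-substitution natural-abundance satellite at +1; the labeled
    species carries the full backbone label and lands in the top channel.
    Label moves signal between channels but never creates or destroys it.
    """
    if not (0.0 <= labeled_fraction <= 1.0):
        raise ValueError("labeled fraction must lie in [0, 1]")
    n_max = c.labelable[isotope]
    pattern = np.zeros(n_max + 1)
    if n_max == 0:
        pattern[0] = 1.0
        return pattern
    na = natural_isotope_fraction(c.formula, isotope)
    light = 1.0 - labeled_fraction
    pattern[0] += light / (1.0 + na)
    pattern[1] += light * na / (1.0 + na)
    pattern[n_max] += labeled_fraction
    return pattern


def lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal noise with mean exactly 1 and the given CV."""
    if cv < 0:
        raise ValueError("noise CV must be >= 0")
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


# ------------------------------------------------------- feature tables

@dataclass
class SimulatedExperiment:
    """Aligned feature table + sample metadata + ground-truth records."""

    features: pd.DataFrame
    samples: pd.DataFrame
    truth: list[dict] = field(default_factory=list)

    def truth_labeled_ids(self) -> set[str]:
        return {t["compound_id"] for t in self.truth if t["is_labeled"]}


DEFAULT_EXPECTED_SHIFTS: tuple[tuple[str, int], ...] = (
    ("13C", 6), ("13C", 4), ("15N", 1),
)


def generate_feature_table(
    design: StudyDesign,
    compounds: list[CompoundSpec] | None = None,
    class_rates: dict[str, float] | None = None,
    noise_cv: float = 0.1,
    n_decoys: int = 5,
    seed: int | None = None,
    plateau: float = 0.95,
) -> SimulatedExperiment:
    """Simulate the aligned LC-MS feature table of a labeling time course.

    One feature row per compound x isotopologue x adduct, plus unlabeled
    decoy compounds. Each decoy also carries a coincidental partner feature
    at one of the expected tracer shifts whose abundance does not differ
    between cohorts, so decoy rejection exercises the statistics rather
    than the m/z matching alone.
    """
    if compounds is not None and len(compounds) == 0:
        raise ValueError("compound list must not be empty")
    if compounds is None:
        compounds = default_panel()
    rates = dict(DEFAULT_CLASS_RATES)
    if class_rates:
        rates.update(class_rates)
    rng = np.random.default_rng(design.seed if seed is None else seed)
    samples = design.samples()
    n_samples = len(samples)

    rows: list[dict] = []
    truth: list[dict] = []
    fid = 0

    def next_fid() -> str:
        nonlocal fid
        fid += 1
        return f"F{fid:05d}"

    for comp in compounds:
        isotope = next(iter(comp.labelable))
        model = EnrichmentModel(rate=rates[comp.compound_class],
                                plateau=plateau)
        base_abundance = 10.0 ** rng.uniform(5.3, 6.3)
        rt = rng.uniform(60.0, 840.0)
        fractions = {
            t: simulate_enrichment(t, model) for t in design.time_points
        }
        feature_ids: dict[str, dict[str, str]] = {}
        for adduct in comp.adducts:
            series = isotopologue_mz_series(comp, adduct, isotope)
            adduct_factor = 1.0 if adduct == "M+H" else rng.uniform(0.1, 0.4)
            # per-sample enrichment and channel pattern
            per_sample_pattern = np.stack([
                isotopologue_pattern(
                    comp, isotope,
                    fractions[t] if g == "labeled" else 0.0,
                )
                for t, g in zip(samples["time_weeks"], samples["group"])
            ])  # (n_samples, n_channels)
            ids_this_adduct: dict[str, str] = {}
            for k, mz in series:
                expect = (base_abundance * adduct_factor
                          * per_sample_pattern[:, k])
                noise = lognormal_noise(rng, noise_cv, n_samples)
                intens = np.where(expect > 0, expect * noise, 0.0)
                if not (intens > 0).any():
                    continue    # a peak picker emits no all-zero feature
                feat_id = next_fid()
                ids_this_adduct[str(k)] = feat_id
                row = {
                    "feature_id": feat_id,
                    "mz": mz * (1.0 + rng.uniform(-1e-6, 1e-6)),
                    "rt_sec": rt + rng.uniform(-0.25, 0.25),
                }
                row.update(dict(zip(samples["sample_id"], intens)))
                rows.append(row)
            feature_ids[adduct] = ids_this_adduct
        truth.append({
            "compound_id": comp.id,
            "name": comp.name,
            "compound_class": comp.compound_class,
            "is_labeled": True,
            "isotope": isotope,
            "label_max": comp.labelable[isotope],
            "labeled_fraction": {f"{t:g}": fractions[t]
                                 for t in design.time_points},
            "feature_ids": feature_ids,
            "rt_sec": rt,
        })

    # Unlabeled decoys: a base feature plus a group-independent coincidental
    # partner at one of the expected tracer shifts.
    for d in range(n_decoys):
        mz0 = rng.uniform(120.0, 800.0)
        rt = rng.uniform(60.0, 840.0)
        abundance = 10.0 ** rng.uniform(5.0, 6.0)
        isotope, count = DEFAULT_EXPECTED_SHIFTS[
            rng.integers(len(DEFAULT_EXPECTED_SHIFTS))
        ]
        shift = count * ISOTOPE_MASS_SHIFT[isotope]
        partner_frac = rng.uniform(0.05, 0.3)
        base_id, partner_id = next_fid(), next_fid()
        for feat_id, mz, frac in (
            (base_id, mz0, 1.0),
            (partner_id, (mz0 + shift) * (1.0 + rng.uniform(-2e-6, 2e-6)),
             partner_frac),
        ):
            intens = abundance * frac * lognormal_noise(rng, noise_cv,
                                                        n_samples)
            row = {"feature_id": feat_id, "mz": mz,
                   "rt_sec": rt + rng.uniform(-0.25, 0.25)}
            row.update(dict(zip(samples["sample_id"], intens)))
            rows.append(row)
        truth.append({
            "compound_id": f"decoy{d + 1}",
            "name": f"decoy {d + 1}",
            "compound_class": "other",
            "is_labeled": False,
            "isotope": isotope,
            "label_max": count,
            "labeled_fraction": {f"{t:g}": 0.0 for t in design.time_points},
            "feature_ids": {"M+H": {"0": base_id, str(count): partner_id}},
            "rt_sec": rt,
        })

    features = pd.DataFrame(rows)
    return SimulatedExperiment(features=features, samples=samples,
                               truth=truth)


def generate_label_distributions(
    design: StudyDesign,
    compounds: list[CompoundSpec] | None = None,
    class_rates: dict[str, float] | None = None,
    noise_cv: float = 0.1,
    seed: int | None = None,
    plateau: float = 0.95,
) -> pd.DataFrame:
    """Long-format isotopologue intensities for the kinetics stage.

    Columns: compound_id, compound_class, sample_id, time_weeks,
    label_count, intensity.
    """
    if compounds is None:
        compounds = default_panel()
    rates = dict(DEFAULT_CLASS_RATES)
    if class_rates:
        rates.update(class_rates)
    rng = np.random.default_rng(design.seed if seed is None else seed)
    samples = design.samples()
    records = []
    for comp in compounds:
        isotope = next(iter(comp.labelable))
        model = EnrichmentModel(rate=rates[comp.compound_class],
                                plateau=plateau)
        abundance = 10.0 ** rng.uniform(5.3, 6.3)
        for s in samples.itertuples(index=False):
            f = (simulate_enrichment(s.time_weeks, model)
                 if s.group == "labeled" else 0.0)
            pattern = isotopologue_pattern(comp, isotope, f)
            noise = lognormal_noise(rng, noise_cv, len(pattern))
            for k, frac in enumerate(pattern):
                records.append({
                    "compound_id": comp.id,
                    "compound_class": comp.compound_class,
                    "sample_id": s.sample_id,
                    "time_weeks": s.time_weeks,
                    "label_count": k,
                    "intensity": abundance * frac * noise[k]
                    if frac > 0 else 0.0,
                })
    return pd.DataFrame(records)


# ------------------------------------------------------------- raw runs

def generate_raw_run(
    compounds: list[CompoundSpec],
    labeled_fractions: dict[str, float] | float,
    peak_models: dict[str, PeakModel] | None = None,
    noise_cv: float = 0.05,
    seed: int = 0,
    scan_interval: float = 0.5,
    duration: float | None = None,
    baseline_peaks_per_scan: int = 2,
    mz_jitter_ppm: float = 3.0,
) -> tuple[RawRun, list[dict]]:
    """Simulate one centroided MS1 run and return it with truth records.

    Each isotopologue of each compound contributes a Gaussian-profiled
    centroid trace at its exact m/z with uniform +-``mz_jitter_ppm``
    instrument jitter; isotopologues of one compound share the RT profile.
    """
    if scan_interval <= 0:
        raise ValueError("scan_interval must be > 0")
    rng = np.random.default_rng(seed)
    peak_models = dict(peak_models or {})
    # assign peak models deterministically for compounds lacking one
    for comp in compounds:
        if comp.id not in peak_models:
            peak_models[comp.id] = PeakModel(
                rt_center=rng.uniform(30.0, 270.0),
                rt_sigma=rng.uniform(2.0, 4.0),
                height=10.0 ** rng.uniform(4.0, 5.0),
                scan_interval=scan_interval,
            )
    if duration is None:
        duration = max(pm.rt_center + 6 * pm.rt_sigma
                       for pm in peak_models.values()) + 5.0
    times = np.arange(0.0, duration, scan_interval)

    truth = []
    traces = []  # (mz_exact, per-scan intensity array)
    for comp in compounds:
        isotope = next(iter(comp.labelable))
        f = (labeled_fractions if isinstance(labeled_fractions, float)
             else labeled_fractions.get(comp.id, 0.0))
        pm = peak_models[comp.id]
        pattern = isotopologue_pattern(comp, isotope, f)
        series = isotopologue_mz_series(comp, comp.adducts[0], isotope)
        channels = {}
        for k, mz in series:
            if pattern[k] <= 0:
                continue
            profile = pm.profile(times) * pattern[k]
            profile = profile * lognormal_noise(rng, noise_cv, len(times))
            traces.append((mz, profile))
            channels[str(k)] = mz
        truth.append({
            "compound_id": comp.id,
            "compound_class": comp.compound_class,
            "is_labeled": f > 0,
            "isotope": isotope,
            "label_max": comp.labelable[isotope],
            "labeled_fraction": f,
            "rt_center": pm.rt_center,
            "channel_mz": channels,
        })

    scans = []
    jit = mz_jitter_ppm * 1e-6
    for i, t in enumerate(times):
        mzs, intens = [], []
        for mz_exact, profile in traces:
            y = profile[i]
            if y < 1.0:       # below single-count detection
                continue
            mzs.append(mz_exact * (1.0 + rng.uniform(-jit, jit)))
            intens.append(y)
        for _ in range(baseline_peaks_per_scan):
            mzs.append(rng.uniform(100.0, 900.0))
            intens.append(rng.exponential(30.0) + 1.0)
        order = np.argsort(mzs)
        scans.append(Scan(time=float(t),
                          mz=np.asarray(mzs)[order],
                          intensity=np.asarray(intens)[order]))
    return RawRun(scans=scans, run_id=f"sim_seed{seed}"), truth


def simulate_eic_pair(
    seed: int,
    n_points: int = 61,
    scan_interval: float = 0.5,
    apex_snr: float = 50.0,
    noise_cv: float = 0.1,
    iso_scale: float = 0.6,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One co-eluting EIC pair (times, base, isotopologue) with noise.

    Both traces share a Gaussian RT profile; the isotopologue is a scaled
    copy. Multiplicative lognormal noise (CV ``noise_cv``) is independent
    between traces; a small additive baseline sets the apex S/N.
    """
    rng = np.random.default_rng(seed)
    times = np.arange(n_points) * scan_interval
    center = times[n_points // 2] + rng.uniform(-scan_interval, scan_interval)
    sigma = rng.uniform(2.0, 4.0)
    height = 5000.0
    clean = height * np.exp(-0.5 * ((times - center) / sigma) ** 2)
    baseline = height / apex_snr
    base = clean * lognormal_noise(rng, noise_cv, n_points) \
        + rng.exponential(baseline, n_points)
    iso = clean * iso_scale * lognormal_noise(rng, noise_cv, n_points) \
        + rng.exponential(baseline * iso_scale, n_points)
    return times, base, iso


# ----------------------------------------------- matched-compartment panel

def generate_compartment_panel(
    n_animals: int = 8,
    n_background: int = 20,
    noise_cv: float = 0.15,
    seed: int = 0,
) -> dict:
    """Matched cortex/urine/serum abundance matrices with planted structure.

    Planted relationships across animals: urinary lysine proportional to
    cortex lysine (positive edge) and urinary albumin anti-proportional to
    cortex lysine (negative edge); background metabolites are independent.
    Creatinine and 24-h urine volume support the diuresis-invariance
    algebra of creatinine normalization.
    """
    rng = np.random.default_rng(seed)
    animals = [f"rat{i + 1}" for i in range(n_animals)]
    cortex_lys = 10.0 ** rng.normal(6.0, 0.25, n_animals)

    def background(prefix, n):
        data = {
            f"{prefix}_bg{j + 1}": 10.0 ** rng.normal(5.5, 0.3, n_animals)
            for j in range(n)
        }
        return data

    cortex = pd.DataFrame(
        {"lysine": cortex_lys, **background("cortex", n_background)},
        index=animals,
    ).T
    urine_lys = 2.0 * cortex_lys * lognormal_noise(rng, noise_cv, n_animals)
    # anti-proportional: albumin falls as cortex lysine rises
    urine_alb = (1e12 / cortex_lys) * lognormal_noise(rng, noise_cv,
                                                      n_animals)
    urine = pd.DataFrame(
        {"lysine": urine_lys, "albumin": urine_alb,
         **background("urine", n_background)},
        index=animals,
    ).T
    serum = pd.DataFrame(background("serum", n_background), index=animals).T

    creatinine = pd.Series(10.0 ** rng.normal(4.0, 0.1, n_animals),
                           index=animals, name="creatinine")
    truth = {
        "positive_edges": [("lysine", "lysine")],
        "negative_edges": [("lysine", "albumin")],
    }
    return {
        "cortex": cortex, "urine": urine, "serum": serum,
        "animals": animals, "creatinine": creatinine, "truth": truth,
    }
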