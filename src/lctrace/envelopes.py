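"""Untargeted mass-difference isotope-envelope detection.

Groups aligned LC-MS features into candidate light/heavy envelopes by exact
tracer mass shift (within a ppm tolerance and a retention-time window around
the light anchor), then retains envelopes whose heavy members are
significantly more abundant in labeled than unlabeled samples: Welch t-test
on log10 intensities, fold-change >= 1.5, p < 0.05 and Benjamini-Hochberg
q < 0.05 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .constants import ISOTOPE_MASS_SHIFT

__all__ = [
    "Feature",
    "EnvelopePartner",
    "IsotopeEnvelope",
    "PartnerTest",
    "EnvelopeParams",
    "group_envelopes",
    "test_envelope",
    "filter_envelopes",
    "detect_labeled_metabolome",
    "features_from_table",
]

DEFAULT_SHIFTS: tuple[tuple[str, int], ...] = (
    ("13C", 6), ("13C", 4), ("15N", 1),
)

INTENSITY_FLOOR = 1.0  # counts; zero/missing intensities are floored here


@dataclass(frozen=True)
class Feature:
    """One aligned LC-MS feature with per-sample intensities."""

    feature_id: str
    mz: float
    rt: float
    intensities: dict[str, float]

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("m/z must be positive")
        if self.rt < 0:
            raise ValueError("retention time must be >= 0")


@dataclass(frozen=True)
class EnvelopePartner:
    feature: Feature
    isotope: str
    label_count: int
    ppm_error: float
    rt_delta: float


@dataclass
class IsotopeEnvelope:
    base: Feature
    partners: list[EnvelopePartner] = field(default_factory=list)


@dataclass
class PartnerTest:
    """Labeled-vs-unlabeled statistics for one heavy partner."""

    envelope: IsotopeEnvelope
    partner: EnvelopePartner
    fold_change: float
    log2_fc: float
    p_value: float
    q_value: float = float("nan")
    floored: bool = False

    def passes(self, fc_min: float, p_max: float, q_max: float) -> bool:
        return (self.fold_change >= fc_min and self.p_value < p_max
                and self.q_value < q_max)


@dataclass(frozen=True)
class EnvelopeParams:
    ppm_tol: float = 10.0
    rt_tol: float = 2.0
    fc_min: float = 1.5
    p_max: float = 0.05
    q_max: float = 0.05
    expected_shifts: tuple[tuple[str, int], ...] = DEFAULT_SHIFTS


def features_from_table(table: pd.DataFrame,
                        samples: pd.DataFrame) -> list[Feature]:
    """Build Feature objects from a feature table + sample sidecar."""
    sample_ids = [s for s in samples["sample_id"] if s in table.columns]
    if not sample_ids:
        raise ValueError("no sample columns found in feature table")
    return [
        Feature(
            feature_id=str(row.feature_id),
            mz=float(row.mz),
            rt=float(row.rt_sec),
            intensities={s: float(getattr(row, s)) for s in sample_ids},
        )
        for row in table.itertuples(index=False)
    ]


def group_envelopes(
    features: list[Feature],
    expected_shifts: tuple[tuple[str, int], ...] = DEFAULT_SHIFTS,
    ppm_tol: float = 10.0,
    rt_tol: float = 2.0,
) -> list[IsotopeEnvelope]:
    """Group features into light/heavy candidate envelopes.

    For each base (light) feature and each expected shift, candidate heavy
    partners lie above the base m/z at base_mz + shift within ``ppm_tol``
    (relative to the base) and within ``rt_tol`` seconds of the base
    feature. Assignment is greedy by ascending |ppm error| per shift, and a
    feature may serve as a partner at most once per shift. Input order does
    not matter: features are canonically sorted first.
    """
    if ppm_tol <= 0 or rt_tol <= 0:
        raise ValueError("tolerances must be positive")
    if not expected_shifts:
        raise ValueError("expected_shifts must be non-empty")
    feats = sorted(features, key=lambda f: (f.mz, f.rt, f.feature_id))
    mzs = np.array([f.mz for f in feats])
    envelopes: dict[str, IsotopeEnvelope] = {}

    for isotope, count in expected_shifts:
        shift = count * ISOTOPE_MASS_SHIFT[isotope]
        candidates = []  # (abs_ppm, base_idx, partner_idx, ppm, rt_delta)
        for i, base in enumerate(feats):
            target = base.mz + shift
            tol = ppm_tol * 1e-6 * base.mz
            lo = np.searchsorted(mzs, target - tol, side="left")
            hi = np.searchsorted(mzs, target + tol, side="right")
            for j in range(lo, hi):
                if j == i:
                    continue
                cand = feats[j]
                rt_delta = cand.rt - base.rt
                if abs(rt_delta) > rt_tol:
                    continue
                ppm = (cand.mz - target) / base.mz * 1e6
                if abs(ppm) > ppm_tol:
                    continue
                candidates.append((abs(ppm), i, j, ppm, rt_delta))
        candidates.sort(key=lambda c: (c[0], feats[c[1]].feature_id,
                                       feats[c[2]].feature_id))
        used_partners: set[int] = set()
        used_bases: set[int] = set()
        for _, i, j, ppm, rt_delta in candidates:
            if j in used_partners or i in used_bases:
                continue
            used_partners.add(j)
            used_bases.add(i)
            base = feats[i]
            env = envelopes.setdefault(base.feature_id,
                                       IsotopeEnvelope(base=base))
            env.partners.append(EnvelopePartner(
                feature=feats[j], isotope=isotope, label_count=count,
                ppm_error=ppm, rt_delta=rt_delta,
            ))
    out = [env for env in envelopes.values() if env.partners]
    out.sort(key=lambda e: e.base.feature_id)
    return out


def _group_values(feature: Feature, sample_ids: list[str]) -> np.ndarray:
    return np.array([feature.intensities.get(s, 0.0) for s in sample_ids])


def test_envelope(
    env: IsotopeEnvelope,
    labeled_samples: list[str],
    unlabeled_samples: list[str],
) -> list[PartnerTest]:
    """Welch t-test per heavy partner on log10 intensities, labeled vs not.

    Fold change is the ratio of raw group means with zero intensities
    floored at 1 count (flagged); the p-value is two-sided with direction
    carried by the fold change.
    """
    if len(labeled_samples) < 2 or len(unlabeled_samples) < 2:
        raise ValueError("need >=2 samples in each group")
    tests = []
    for partner in env.partners:
        lab = _group_values(partner.feature, labeled_samples)
        unl = _group_values(partner.feature, unlabeled_samples)
        floored = bool((lab < INTENSITY_FLOOR).any()
                       or (unl < INTENSITY_FLOOR).any())
        lab_f = np.maximum(lab, INTENSITY_FLOOR)
        unl_f = np.maximum(unl, INTENSITY_FLOOR)
        fc = lab_f.mean() / unl_f.mean()
        log_lab, log_unl = np.log10(lab_f), np.log10(unl_f)
        if log_lab.std() == 0 and log_unl.std() == 0:
            p = 1.0 if log_lab.mean() == log_unl.mean() else 0.0
        else:
            p = float(stats.ttest_ind(log_lab, log_unl,
                                      equal_var=False).pvalue)
        tests.append(PartnerTest(
            envelope=env, partner=partner, fold_change=float(fc),
            log2_fc=float(np.log2(fc)), p_value=p, floored=floored,
        ))
    return tests


def filter_envelopes(
    tests: list[PartnerTest],
    fc_min: float = 1.5,
    p_max: float = 0.05,
    q_max: float = 0.05,
) -> list[IsotopeEnvelope]:
    """BH-correct over all tested partners and retain passing envelopes.

    The q-value family is every tested partner in the run. An envelope is
    retained iff at least one partner meets fold-change, p and q thresholds
    in the labeled direction; output is sorted by its best partner q.
    """
    if not tests:
        return []
    pvals = np.array([t.p_value for t in tests])
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    for t, q in zip(tests, qvals):
        t.q_value = float(q)
    best_q: dict[int, tuple[float, IsotopeEnvelope]] = {}
    for t in tests:
        if t.passes(fc_min, p_max, q_max):
            key = id(t.envelope)
            if key not in best_q or t.q_value < best_q[key][0]:
                best_q[key] = (t.q_value, t.envelope)
    retained = sorted(best_q.values(), key=lambda x: (x[0],
                                                      x[1].base.feature_id))
    return [env for _, env in retained]


def detect_labeled_metabolome(
    table: pd.DataFrame,
    samples: pd.DataFrame,
    params: EnvelopeParams = EnvelopeParams(),
) -> pd.DataFrame:
    """End-to-end untargeted detection: group -> test -> filter.

    Returns a report with one row per tested partner, flagging which were
    retained; rows carry base m/z, RT, shift identity, FC, p and q.
    """
    if "group" not in samples.columns:
        raise ValueError("sample metadata must carry a 'group' column")
    features = features_from_table(table, samples)
    envelopes = group_envelopes(features, params.expected_shifts,
                                params.ppm_tol, params.rt_tol)
    labeled = list(samples.loc[samples["group"] == "labeled", "sample_id"])
    unlabeled = list(samples.loc[samples["group"] == "unlabeled",
                                 "sample_id"])
    all_tests: list[PartnerTest] = []
    for env in envelopes:
        all_tests.extend(test_envelope(env, labeled, unlabeled))
    retained_envs = {id(env) for env in filter_envelopes(
        all_tests, params.fc_min, params.p_max, params.q_max)}
    rows = []
    for t in all_tests:
        rows.append({
            "base_feature": t.envelope.base.feature_id,
            "base_mz": t.envelope.base.mz,
            "base_rt": t.envelope.base.rt,
            "partner_feature": t.partner.feature.feature_id,
            "isotope": t.partner.isotope,
            "label_count": t.partner.label_count,
            "ppm_error": t.partner.ppm_error,
            "rt_delta": t.partner.rt_delta,
            "fold_change": t.fold_change,
            "log2_fc": t.log2_fc,
            "p_value": t.p_value,
            "q_value": t.q_value,
            "floored": t.floored,
            "partner_pass": t.passes(params.fc_min, params.p_max,
                                     params.q_max),
            "envelope_retained": id(t.envelope) in retained_envs,
        })
    report = pd.DataFrame(rows)
    if not report.empty:
        report = report.sort_values(
            ["envelope_retained", "q_value"], ascending=[False, True]
        ).reset_index(drop=True)
    return report
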