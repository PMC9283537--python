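"""Untargeted envelope grouping, Welch testing, BH filtering, end-to-end."""

import itertools
import math

import numpy as np
import pytest

from lctrace.constants import ISOTOPE_MASS_SHIFT
from lctrace.envelopes import (
    DEFAULT_SHIFTS,
    EnvelopeParams,
    Feature,
    IsotopeEnvelope,
    EnvelopePartner,
    PartnerTest,
    detect_labeled_metabolome,
    filter_envelopes,
    group_envelopes,
)
from lctrace.envelopes import test_envelope as run_envelope_test
from lctrace.simulate import StudyDesign, generate_feature_table


def feat(fid, mz, rt, intensities=None):
    return Feature(feature_id=fid, mz=mz, rt=rt,
                   intensities=intensities or {})


def brute_force_group(features, expected_shifts, ppm_tol, rt_tol):
    """Exhaustive O(n^2) pair-enumeration oracle for envelope grouping."""
    feats = sorted(features, key=lambda f: (f.mz, f.rt, f.feature_id))
    result = {}
    for isotope, count in expected_shifts:
        shift = count * ISOTOPE_MASS_SHIFT[isotope]
        pairs = []
        for base, cand in itertools.permutations(feats, 2):
            target = base.mz + shift
            ppm = (cand.mz - target) / base.mz * 1e6
            rt_delta = cand.rt - base.rt
            if abs(ppm) <= ppm_tol and abs(rt_delta) <= rt_tol:
                pairs.append((abs(ppm), base.feature_id, cand.feature_id))
        pairs.sort()
        used_partner, used_base = set(), set()
        for _, b, c in pairs:
            if c in used_partner or b in used_base:
                continue
            used_partner.add(c)
            used_base.add(b)
            result.setdefault(b, []).append((isotope, count, c))
    return result


def envelopes_as_dict(envs):
    return {
        e.base.feature_id: sorted(
            (p.isotope, p.label_count, p.feature.feature_id)
            for p in e.partners
        )
        for e in envs
    }


class TestGrouping:
    def test_lysine_pair_grouped(self):
        base = feat("a", 147.1128, 300.0)
        cand = feat("b", 153.1329, 300.5)
        envs = group_envelopes([base, cand])
        assert len(envs) == 1
        p = envs[0].partners[0]
        assert (p.isotope, p.label_count) == ("13C", 6)
        assert abs(p.ppm_error) < 1.0

    def test_rt_beyond_tolerance_not_grouped(self):
        base = feat("a", 147.1128, 300.0)
        cand = feat("b", 153.1329, 302.5)
        assert group_envelopes([base, cand]) == []

    def test_smallest_ppm_candidate_wins(self):
        shift = 6 * ISOTOPE_MASS_SHIFT["13C"]
        base = feat("a", 147.1128, 300.0)
        # 1 ppm vs 4 ppm errors relative to the base m/z
        good = feat("b", 147.1128 + shift + 1e-6 * 147.1128, 300.0)
        bad = feat("c", 147.1128 + shift + 4e-6 * 147.1128, 300.1)
        envs = group_envelopes([base, bad, good])
        ids = [p.feature.feature_id for p in envs[0].partners
               if (p.isotope, p.label_count) == ("13C", 6)]
        assert ids == ["b"]

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        feats = [feat(f"f{i}", rng.uniform(100, 500), rng.uniform(0, 600))
                 for i in range(60)]
        shift = 4 * ISOTOPE_MASS_SHIFT["13C"]
        feats += [feat(f"p{i}", feats[i].mz + shift, feats[i].rt)
                  for i in range(10)]
        a = envelopes_as_dict(group_envelopes(feats))
        rng.shuffle(feats)
        b = envelopes_as_dict(group_envelopes(feats))
        assert a == b

    def test_monotone_in_tolerances(self):
        rng = np.random.default_rng(1)
        feats = [feat(f"f{i}", rng.uniform(100, 300), rng.uniform(5, 100))
                 for i in range(40)]
        shift = ISOTOPE_MASS_SHIFT["15N"]
        feats += [feat(f"p{i}",
                       feats[i].mz + shift + rng.uniform(-5e-6, 5e-6)
                       * feats[i].mz,
                       feats[i].rt + rng.uniform(-3, 3))
                  for i in range(20)]
        def count(ppm, rt):
            return sum(len(e.partners) for e in
                       group_envelopes(feats, ppm_tol=ppm, rt_tol=rt))
        assert count(10, 2) >= count(5, 2) >= count(2, 2)
        assert count(10, 2) >= count(10, 1) >= count(10, 0.5)

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ValueError):
            group_envelopes([], ppm_tol=0)

    def test_agrees_with_bruteforce_oracle(self):
        """Greedy sorted-array grouping equals exhaustive O(n^2)
        enumeration on 30 random small tables."""
        for seed in range(30):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(5, 25))
            feats = [feat(f"f{i}", float(rng.uniform(100, 400)),
                          float(rng.uniform(5, 60)))
                     for i in range(n)]
            # sprinkle near-shift partners to make matches likely
            for i in range(n // 3):
                iso, cnt = DEFAULT_SHIFTS[int(rng.integers(3))]
                shift = cnt * ISOTOPE_MASS_SHIFT[iso]
                feats.append(feat(
                    f"g{i}",
                    feats[i].mz + shift
                    + float(rng.uniform(-12e-6, 12e-6)) * feats[i].mz,
                    feats[i].rt + float(rng.uniform(-3, 3)),
                ))
            got = envelopes_as_dict(group_envelopes(feats))
            oracle = {
                b: sorted((iso, cnt, c) for iso, cnt, c in partners)
                for b, partners in brute_force_group(
                    feats, DEFAULT_SHIFTS, 10.0, 2.0).items()
            }
            assert got == oracle, f"seed {seed}"


def _welch_by_hand(x, y):
    """Textbook Welch statistic and df on already-transformed values."""
    nx, ny = len(x), len(y)
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    t = (np.mean(x) - np.mean(y)) / math.sqrt(vx / nx + vy / ny)
    df = (vx / nx + vy / ny) ** 2 / (
        (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return t, df


class TestEnvelopeTest:
    def _env(self, partner_values):
        base = feat("b", 150.0, 10.0, {k: 100.0 for k in partner_values})
        part = feat("p", 156.02, 10.0, partner_values)
        env = IsotopeEnvelope(base=base)
        env.partners.append(EnvelopePartner(
            feature=part, isotope="13C", label_count=6, ppm_error=0.5,
            rt_delta=0.0))
        return env

    def test_identical_groups_null(self):
        vals = {"l1": 50.0, "l2": 50.0, "u1": 50.0, "u2": 50.0}
        env = self._env(vals)
        [t] = run_envelope_test(env, ["l1", "l2"], ["u1", "u2"])
        assert t.fold_change == pytest.approx(1.0)
        assert t.p_value == 1.0

    def test_welch_example(self):
        vals = {"l1": 1000.0, "l2": 1100.0, "l3": 900.0,
                "u1": 10.0, "u2": 12.0, "u3": 9.0}
        env = self._env(vals)
        [t] = run_envelope_test(env, ["l1", "l2", "l3"], ["u1", "u2", "u3"])
        assert t.fold_change == pytest.approx(1000 / (31 / 3), rel=1e-6)
        assert t.fold_change == pytest.approx(96.8, abs=0.1)
        assert t.p_value < 0.01
        # independent hand computation on the log10 scale
        from scipy import stats as sps
        th, df = _welch_by_hand(np.log10([1000, 1100, 900]),
                                np.log10([10, 12, 9]))
        p_hand = 2 * sps.t.sf(abs(th), df)
        assert t.p_value == pytest.approx(p_hand, rel=1e-6)

    def test_zero_unlabeled_floored(self):
        vals = {"l1": 1000.0, "l2": 1200.0, "u1": 0.0, "u2": 0.0}
        env = self._env(vals)
        [t] = run_envelope_test(env, ["l1", "l2"], ["u1", "u2"])
        assert t.floored
        assert t.fold_change == pytest.approx(1100.0)  # mean / floor 1

    def test_too_few_samples_rejected(self):
        env = self._env({"l1": 1.0, "u1": 1.0, "u2": 2.0})
        with pytest.raises(ValueError):
            run_envelope_test(env, ["l1"], ["u1", "u2"])


def _mk_test(p, fc, envelope=None):
    env = envelope or IsotopeEnvelope(base=feat("b", 100.0, 1.0, {}))
    partner = EnvelopePartner(
        feature=feat("p", 106.02, 1.0, {}), isotope="13C", label_count=6,
        ppm_error=0.0, rt_delta=0.0)
    return PartnerTest(envelope=env, partner=partner, fold_change=fc,
                       log2_fc=math.log2(fc), p_value=p)


class TestFilter:
    def test_all_thresholds_met_retained(self):
        assert len(filter_envelopes([_mk_test(0.04, 2.0)])) == 1

    def test_fc_below_threshold_rejected(self):
        assert filter_envelopes([_mk_test(0.001, 1.4)]) == []

    def test_empty_input_empty_output(self):
        assert filter_envelopes([]) == []

    def test_q_monotone_in_p(self):
        rng = np.random.default_rng(4)
        tests = [_mk_test(float(p), 2.0) for p in rng.uniform(0, 1, 50)]
        filter_envelopes(tests)
        by_p = sorted(tests, key=lambda t: t.p_value)
        qs = [t.q_value for t in by_p]
        assert all(b >= a for a, b in zip(qs, qs[1:]))
        assert all(t.q_value >= t.p_value for t in tests)

    def test_bh_controls_null_decoys(self):
        """With 20 uniform-null decoy partners, BH at q<=0.05 retains
        on average at most ~1 over 200 replicates."""
        rng = np.random.default_rng(123)
        total = 0
        for _ in range(200):
            tests = [_mk_test(float(p), 2.0)
                     for p in rng.uniform(0, 1, 20)]
            total += len(filter_envelopes(tests))
        assert total / 200 <= 1.0


def _recovered_and_decoys(exp, report):
    retained = report[report.envelope_retained]
    base2cid = {}
    for t in exp.truth:
        for by_adduct in t["feature_ids"].values():
            base2cid[by_adduct["0"]] = (t["compound_id"], t["is_labeled"])
    found = {base2cid[b] for b in retained.base_feature.unique()
             if b in base2cid}
    recovered = {c for c, lab in found if lab}
    decoys = {c for c, lab in found if not lab}
    return recovered, decoys


class TestEndToEnd:
    def test_standard_experiment_full_recovery(self, standard_experiment):
        report = detect_labeled_metabolome(standard_experiment.features,
                                           standard_experiment.samples)
        recovered, decoys = _recovered_and_decoys(standard_experiment,
                                                  report)
        assert recovered == standard_experiment.truth_labeled_ids()
        assert decoys == set()

    def test_all_unlabeled_detects_nothing(self):
        design = StudyDesign(seed=5)
        exp = generate_feature_table(design, noise_cv=0.1, n_decoys=5,
                                     seed=5, plateau=0.0)
        report = detect_labeled_metabolome(exp.features, exp.samples)
        assert report.empty or not report.envelope_retained.any()

    def test_detection_is_presence_based(self):
        """Recovery at a 0.5 plateau equals recovery at 0.95: detection
        keys on presence of the heavy channel, not its magnitude."""
        sets = []
        for plateau in (0.5, 0.95):
            exp = generate_feature_table(StudyDesign(seed=9), noise_cv=0.1,
                                         n_decoys=5, seed=9,
                                         plateau=plateau)
            report = detect_labeled_metabolome(exp.features, exp.samples)
            recovered, _ = _recovered_and_decoys(exp, report)
            sets.append(recovered)
        assert sets[0] == sets[1]

    def test_sensitivity_across_seeds(self):
        """noise CV <= 0.2, enrichment >= 0.3: perfect sensitivity and
        zero decoy retention across 20 seeds."""
        for seed in range(20):
            exp = generate_feature_table(StudyDesign(seed=seed),
                                         noise_cv=0.1, n_decoys=5,
                                         seed=seed)
            report = detect_labeled_metabolome(exp.features, exp.samples)
            recovered, decoys = _recovered_and_decoys(exp, report)
            assert recovered == exp.truth_labeled_ids(), f"seed {seed}"
            assert decoys == set(), f"seed {seed}"

    def test_missing_group_metadata_rejected(self, standard_experiment):
        samples = standard_experiment.samples.drop(columns=["group"])
        with pytest.raises(ValueError):
            detect_labeled_metabolome(standard_experiment.features, samples)
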