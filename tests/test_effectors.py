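"""Complex co-regulation scoring and motif-based substrate prediction."""

import math

import numpy as np
import pandas as pd
import pytest

from phosphatlas import effectors as ef
from phosphatlas.types import ComplexCatalog


def cond_values(n=200, seed=0):
    rng = np.random.default_rng(seed)
    return pd.Series(rng.normal(size=n), index=[f"P{i:03d}_S1" for i in range(n)])


class TestComplexRegulation:
    def test_sign_follows_mean_fold_change(self):
        vals = cond_values()
        down = {f"P{i:03d}_S1" for i in range(5)}
        vals[list(down)] = [-3.0, -2.5, -3.5, -2.8, -3.1]
        score = ef.complex_regulation(vals, down)
        assert score < 0

    def test_shifted_complex_scores_large(self):
        vals = cond_values(seed=1)
        shifted = {f"P{i:03d}_S1" for i in range(8)}
        vals[list(shifted)] = vals[list(shifted)] + 3.0
        score = ef.complex_regulation(vals, shifted)
        assert abs(score) > 2.0

    def test_too_few_sites_missing(self):
        vals = cond_values()
        assert math.isnan(ef.complex_regulation(vals, {"P000_S1", "P001_S1"},
                                                min_sites=3))

    def test_h0_pvalues_superuniform(self):
        rng = np.random.default_rng(2)
        n_small = 0
        reps = 400
        for _ in range(reps):
            vals = pd.Series(rng.normal(size=120),
                             index=[f"P{i:03d}_S1" for i in range(120)])
            cs = set(rng.choice(vals.index, size=6, replace=False).tolist())
            score = ef.complex_regulation(vals, cs)
            p = 10 ** (-abs(score))
            n_small += p <= 0.05
        se = math.sqrt(0.05 * 0.95 / reps)
        assert n_small / reps <= 0.05 + 3 * se

    def test_sign_symmetry_under_negation(self):
        vals = cond_values(seed=3)
        cs = set(vals.index[:6])
        a = ef.complex_regulation(vals, cs)
        b = ef.complex_regulation(-vals, cs)
        assert a == pytest.approx(-b)


class TestKinaseComplexAssociation:
    def test_identical_profiles_give_r_one(self, small_atlas, small_matrix, small_truth):
        assoc = ef.kinase_complex_association(
            small_atlas, small_matrix, small_truth.catalog,
            exclude_kinase_substrates=False,
        )
        assert len(assoc)
        assert assoc["r"].abs().max() <= 1.0 + 1e-12

    def test_coupled_pairs_rank_above_uncoupled(self, small_atlas, small_matrix,
                                                small_truth):
        from phosphatlas.atlas import rank_auc

        assoc = ef.kinase_complex_association(
            small_atlas, small_matrix, small_truth.catalog,
            sets=small_truth.revealed_sets, exclude_kinase_substrates=True,
        )
        truth = small_truth.couplings
        is_true = np.array(
            [(k, c) in truth for k, c in zip(assoc["kinase"], assoc["complex"])]
        )
        if is_true.sum() == 0:
            pytest.skip("no coupled pair scored in the small fixture")
        score = -np.log10(assoc["q"].to_numpy() + 1e-300)
        auc = rank_auc(score[is_true], score[~is_true])
        assert auc >= 0.8

    def test_substrate_exclusion_locality(self, small_matrix, small_truth):
        """Removing a kinase's substrates only changes complexes hosting them."""
        kin = small_truth.kinases[0]
        sub_tokens = {str(s) for s in small_truth.revealed_sets.sets[kin]}
        base = ef.complex_regulation_matrix(small_matrix, small_truth.catalog)
        excl = ef.complex_regulation_matrix(
            small_matrix, small_truth.catalog, exclude_sites=sub_tokens
        )
        sites_map = ef.complex_sites_map(small_matrix.index, small_truth.catalog)
        for cid in small_truth.catalog.complexes:
            touched = bool(sites_map[cid] & sub_tokens)
            if not touched:
                a, b = base.scores.loc[cid], excl.scores.loc[cid]
                pd.testing.assert_series_equal(a, b)

    def test_false_discoveries_controlled_on_noise(self):
        rng = np.random.default_rng(4)
        acts = pd.DataFrame(rng.normal(size=(6, 40)),
                            index=[f"K{i}" for i in range(6)],
                            columns=[f"c{j}" for j in range(40)])
        sites = [f"P{i:03d}_S1" for i in range(150)]
        matrix = pd.DataFrame(rng.normal(size=(150, 40)), index=sites,
                              columns=acts.columns)
        catalog = ComplexCatalog({
            f"CPX{i}": frozenset({f"P{j:03d}" for j in range(i * 10, i * 10 + 5)})
            for i in range(10)
        })
        assoc = ef.kinase_complex_association(
            acts, matrix, catalog, exclude_kinase_substrates=False
        )
        assert (assoc["q"] < 0.05).sum() <= max(2, 0.05 * len(assoc))


class TestPpvFdrCurve:
    def _assoc(self, qs, truth_flags):
        return (
            pd.DataFrame({
                "kinase": [f"K{i}" for i in range(len(qs))],
                "complex": [f"C{i}" for i in range(len(qs))],
                "q": qs,
            }),
            {(f"K{i}", f"C{i}") for i, t in enumerate(truth_flags) if t},
        )

    def test_all_true_predictions_ppv_one(self):
        assoc, truth = self._assoc([0.01, 0.02, 0.3], [1, 1, 1])
        curve = ef.ppv_fdr_curve(assoc, truth)
        assert (curve["ppv"] == 1.0).all()

    def test_random_ranking_matches_baseline(self):
        rng = np.random.default_rng(5)
        flags = rng.random(400) < 0.3
        qs = np.sort(rng.random(400))
        assoc, truth = self._assoc(qs, flags)
        curve = ef.ppv_fdr_curve(assoc, truth)
        tail = curve.iloc[-1]
        assert tail["ppv"] == pytest.approx(tail["baseline"], abs=0.01)
        mid = curve[curve["n_predictions"] >= 100].iloc[0]
        se = math.sqrt(0.3 * 0.7 / mid["n_predictions"])
        assert abs(mid["ppv"] - 0.3) <= 3 * se


class TestPwm:
    def test_identical_flanks_zero_pseudocount(self):
        pwm = ef.build_pwm(["AAASAAA"] * 5, w=3, pseudocount=0.0)
        assert pwm.freq.loc[-3, "A"] == 1.0
        # every position is an indicator: information = ln 20
        assert np.allclose(pwm.info.to_numpy(), math.log(20.0))

    def test_uniform_flanks_zero_information(self):
        flanks = [aa * 3 + "S" + aa * 3 for aa in ef.AMINO_ACIDS]
        pwm = ef.build_pwm(flanks, w=3, pseudocount=0.0)
        off = [p for p in pwm.position_range() if p != 0]
        assert np.allclose(pwm.info.loc[off].to_numpy(), 0.0, atol=1e-12)

    def test_frequencies_match_hand_counts(self):
        flanks = ["ACSTG", "ACSTG", "GCSTA", "ACSWG", "ACSTG"]
        pwm = ef.build_pwm(flanks, w=2, pseudocount=0.0)
        assert pwm.freq.loc[-2, "A"] == pytest.approx(4 / 5)
        assert pwm.freq.loc[-2, "G"] == pytest.approx(1 / 5)
        assert pwm.freq.loc[1, "T"] == pytest.approx(4 / 5)
        assert pwm.freq.loc[1, "W"] == pytest.approx(1 / 5)

    def test_padding_excluded_with_renormalization(self):
        pwm = ef.build_pwm(["__ASA__", "__GSG__"], w=3, pseudocount=0.0)
        assert pwm.freq.loc[-1, "A"] == pytest.approx(0.5)
        assert pwm.freq.loc[-1, "G"] == pytest.approx(0.5)
        # padded-only positions fall back to uniform after pseudocount... all-zero
        assert np.isfinite(pwm.freq.loc[-3].to_numpy()).all()

    def test_row_sums_one(self, small_truth, small_flanks):
        k = small_truth.kinases[0]
        flanks = [small_flanks.flanks[s] for s in small_truth.substrate_sets[k]]
        pwm = ef.build_pwm(flanks, w=small_flanks.window)
        assert np.allclose(pwm.freq.sum(axis=1).to_numpy(), 1.0)
        assert (pwm.info >= 0).all()


def consensus_of(pwm):
    return "".join(
        pwm.freq.loc[p].idxmax() if p != 0 else "S" for p in pwm.position_range()
    )


def anticonsensus_of(pwm):
    return "".join(
        pwm.freq.loc[p].idxmin() if p != 0 else "S" for p in pwm.position_range()
    )


@pytest.fixture(scope="module")
def demo_pwm():
    rng = np.random.default_rng(6)
    flanks = []
    for _ in range(30):
        flank = "".join(
            "R" if pos in (-3, -5) and rng.random() < 0.8
            else ("S" if pos == 0 else str(rng.choice(list(ef.AMINO_ACIDS))))
            for pos in range(-7, 8)
        )
        flanks.append(flank)
    return ef.build_pwm(flanks, w=7)


class TestMotifScores:
    def test_logweights_consensus_and_worst(self, demo_pwm):
        assert ef.score_logweights(consensus_of(demo_pwm), demo_pwm) == pytest.approx(1.0)
        assert ef.score_logweights(anticonsensus_of(demo_pwm), demo_pwm) == pytest.approx(0.0)

    def test_mss_consensus_and_anticonsensus(self, demo_pwm):
        assert ef.score_mss(consensus_of(demo_pwm), demo_pwm) == pytest.approx(1.0)
        assert ef.score_mss(anticonsensus_of(demo_pwm), demo_pwm) == pytest.approx(0.0)
        rng = np.random.default_rng(7)
        for _ in range(20):
            flank = "".join(
                "S" if p == 0 else str(rng.choice(list(ef.AMINO_ACIDS)))
                for p in range(-7, 8)
            )
            assert 0.0 <= ef.score_mss(flank, demo_pwm) <= 1.0

    def test_raw_and_normalized_logweights_order_identically(self, demo_pwm):
        rng = np.random.default_rng(8)
        flanks = [
            "".join("S" if p == 0 else str(rng.choice(list(ef.AMINO_ACIDS)))
                    for p in range(-7, 8))
            for _ in range(10)
        ]
        logf = np.log(demo_pwm.freq)
        raws = [
            sum(logf.loc[p, aa] for p, aa in zip(demo_pwm.position_range(), f)
                if p != 0)
            for f in flanks
        ]
        norms = [ef.score_logweights(f, demo_pwm) for f in flanks]
        assert np.argsort(raws).tolist() == np.argsort(norms).tolist()

    def test_substitution_toward_consensus_never_decreases_mss(self, demo_pwm):
        rng = np.random.default_rng(9)
        cons = consensus_of(demo_pwm)
        for _ in range(25):
            flank = list(
                "S" if p == 0 else str(rng.choice(list(ef.AMINO_ACIDS)))
                for p in range(-7, 8)
            )
            before = ef.score_mss("".join(flank), demo_pwm)
            pos = int(rng.integers(0, 15))
            if pos == 7:
                continue
            flank[pos] = cons[pos]
            after = ef.score_mss("".join(flank), demo_pwm)
            assert after >= before - 1e-12

    def test_uniform_pwm_degenerate_zero(self):
        flanks = [aa * 3 + "S" + aa * 3 for aa in ef.AMINO_ACIDS]
        pwm = ef.build_pwm(flanks, w=3, pseudocount=0.0)
        assert ef.score_mss("AAASAAA", pwm) == 0.0

    def test_padding_skipped_consistently(self, demo_pwm):
        cons = consensus_of(demo_pwm)
        padded = "__" + cons[2:]
        full = ef.score_mss(cons, demo_pwm)
        part = ef.score_mss(padded, demo_pwm)
        assert part == pytest.approx(1.0)  # remaining positions still consensus
        assert full == pytest.approx(1.0)


class TestSiteCoregulation:
    def test_identical_profiles(self):
        prof = pd.Series(np.arange(12, dtype=float), index=[f"c{i}" for i in range(12)])
        r, p, n = ef.site_coregulation(prof, prof)
        assert r == pytest.approx(1.0)
        assert n == 12

    def test_insufficient_shared_conditions(self):
        a = pd.Series([1.0] * 5, index=[f"c{i}" for i in range(5)])
        r, p, n = ef.site_coregulation(a, a, min_shared=10)
        assert math.isnan(r) and n == 5


class TestPredictAndShortlist:
    def test_pipeline_recovers_heldout_substrates(self, small_truth, small_matrix,
                                                  small_atlas, small_flanks):
        from phosphatlas.atlas import rank_auc

        k = small_truth.kinases[0]
        preds = ef.predict_substrates(
            k, small_atlas, small_matrix, small_flanks,
            small_truth.revealed_sets, min_shared=8,
        )
        held_out = {
            str(s)
            for s in small_truth.substrate_sets[k] - small_truth.revealed_sets.sets[k]
        }
        scored = preds.dropna(subset=["coregulation_r"])
        flags = scored["site"].isin(held_out).to_numpy()
        if flags.sum() == 0:
            pytest.skip("no held-out substrate quantified in small fixture")
        combo = scored["mss"].to_numpy() + scored["coregulation_r"].to_numpy()
        assert rank_auc(combo[flags], combo[~flags]) > 0.7

    def test_shortlist_is_bruteforce_intersection(self):
        rng = np.random.default_rng(10)
        preds = pd.DataFrame({
            "site": [f"P{i}_S1" for i in range(50)],
            "logweights": rng.random(50),
            "mss": rng.random(50),
            "coregulation_r": rng.uniform(-1, 1, 50),
            "coregulation_p": rng.random(50),
            "inhibition_log2": rng.normal(0, 1, 50),
        })
        out = ef.shortlist_targets(
            preds, coreg_p_max=0.2, logweights_min=0.5, mss_min=0.4,
            inhibition_max=-0.2,
        )
        brute = preds[
            (preds["coregulation_p"] < 0.2)
            & (preds["coregulation_r"] > 0)
            & (preds["logweights"] > 0.5)
            & (preds["mss"] > 0.4)
            & (preds["inhibition_log2"] < -0.2)
        ]
        assert out["site"].tolist() == brute["site"].tolist()

    def test_all_filters_disabled_is_identity(self):
        preds = pd.DataFrame({
            "site": ["A_S1", "B_S2"],
            "logweights": [0.1, 0.9],
            "mss": [0.2, 0.8],
            "coregulation_r": [-0.5, 0.5],
            "coregulation_p": [0.9, 0.001],
        })
        out = ef.shortlist_targets(preds, coreg_p_max=None, logweights_min=None,
                                   mss_min=None)
        assert len(out) == 2

    def test_single_failing_filter_excludes(self):
        preds = pd.DataFrame({
            "site": ["A_S1"],
            "logweights": [0.95],
            "mss": [0.9],
            "coregulation_r": [0.8],
            "coregulation_p": [0.5],  # fails the p filter
        })
        assert ef.shortlist_targets(preds, coreg_p_max=0.01, logweights_min=0.8,
                                    mss_min=0.6).empty
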