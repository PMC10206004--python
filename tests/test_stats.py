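"""Reliability / validity statistics against independent oracles."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from notescore.scoring import EpisodeScore, ResponderClassification
from notescore.stats import (
    DegenerateStatisticError,
    InsufficientDataError,
    _bca_interval,
    bootstrap_ci_bca,
    dice_per_category,
    fit_multinomial_logit,
    icc_2k,
    krippendorff_alpha,
    responder_rate_table,
    round_half_up,
    spearman_rho,
)

# ---------------------------------------------------------------------------
# Brute-force oracles (independent of the implementation's coincidence
# matrix / ANOVA code paths)
# ---------------------------------------------------------------------------


def alpha_oracle_ordinal(matrix):
    """Krippendorff's alpha by explicit pairwise enumeration."""
    arr = np.asarray(matrix, dtype=float)
    pooled = []
    # margins n_c over all pairable values
    units = []
    for row in arr:
        obs = [v for v in row if not np.isnan(v)]
        if len(obs) >= 2:
            units.append(obs)
            pooled.extend(obs)
    values = sorted(set(pooled))
    n_c = {v: pooled.count(v) for v in values}

    def delta2(c, d):
        lo, hi = sorted((c, d))
        s = sum(n_c[g] for g in values if lo <= g <= hi) - (n_c[c] + n_c[d]) / 2
        return s * s

    n = len(pooled)
    d_obs = 0.0
    for obs in units:
        m = len(obs)
        for i in range(m):
            for j in range(m):
                if i != j:
                    d_obs += delta2(obs[i], obs[j]) / (m - 1)
    d_obs /= n
    d_exp = 0.0
    for i in range(n):
        for j in range(n):
            if i != j:
                d_exp += delta2(pooled[i], pooled[j])
    d_exp /= n * (n - 1)
    return 1.0 - d_obs / d_exp


class TestKrippendorffAlpha:
    def test_perfect_agreement(self):
        m = np.array([[1, 1], [2, 2], [3, 3], [2, 2], [1, 1]], dtype=float)
        assert krippendorff_alpha(m) == pytest.approx(1.0)

    def test_matches_bruteforce_oracle_with_missing(self):
        m = np.array(
            [
                [1, 1], [2, 2], [3, 3], [2, 2], [1, 2],  # one disagreement
                [np.nan, 2], [3, np.nan], [1, 1], [2, 2], [3, 3],
            ],
            dtype=float,
        )
        assert krippendorff_alpha(m) == pytest.approx(alpha_oracle_ordinal(m), abs=1e-9)

    @pytest.mark.parametrize("n_units", [12, 20])
    def test_matches_oracle_on_random_matrices(self, n_units):
        rng = np.random.default_rng(7)
        for _ in range(5):
            m = rng.integers(1, 4, size=(n_units, 3)).astype(float)
            m[rng.random(m.shape) < 0.15] = np.nan
            if np.isnan(m).all():
                continue
            assert krippendorff_alpha(m) == pytest.approx(
                alpha_oracle_ordinal(m), abs=1e-9
            )

    def test_independent_ratings_near_zero(self):
        rng = np.random.default_rng(11)
        m = rng.integers(1, 4, size=(10_000, 2)).astype(float)
        assert abs(krippendorff_alpha(m)) < 0.03

    def test_na_codes_treated_as_missing(self):
        m = np.array([[1, 1], [0, 1], [2, 2], [3, 3], [0.5, 2]], dtype=float)
        expect = np.array(
            [[1, 1], [np.nan, 1], [2, 2], [3, 3], [np.nan, 2]], dtype=float
        )
        assert krippendorff_alpha(m) == pytest.approx(alpha_oracle_ordinal(expect))

    def test_all_missing_is_error(self):
        with pytest.raises(DegenerateStatisticError):
            krippendorff_alpha(np.full((4, 2), np.nan))

    def test_unit_permutation_invariant(self):
        rng = np.random.default_rng(3)
        m = rng.integers(1, 4, size=(15, 2)).astype(float)
        perm = rng.permutation(15)
        assert krippendorff_alpha(m) == pytest.approx(krippendorff_alpha(m[perm]))


class TestIcc2k:
    def test_perfect_agreement_is_one(self):
        m = np.array([[1, 1], [2, 2], [3, 3], [1, 1], [2, 2]], dtype=float)
        icc, p = icc_2k(m)
        assert icc == pytest.approx(1.0)
        assert p < 0.001

    def test_constant_matrix_degenerate(self):
        with pytest.raises(DegenerateStatisticError):
            icc_2k(np.full((5, 2), 2.0))

    def test_too_few_units(self):
        with pytest.raises(InsufficientDataError):
            icc_2k(np.array([[1, 1], [2, 2]], dtype=float))

    def test_matches_pingouin_on_random_matrix(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        m = rng.integers(1, 4, size=(20, 2)).astype(float)
        icc, p = icc_2k(m)
        long = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(20), 2),
                "raters": np.tile(["A", "B"], 20),
                "scores": m.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(
            long, targets="targets", raters="raters", ratings="scores"
        ).set_index("Type")
        # "ICC(A,k)": two-way random effects, average measures
        assert icc == pytest.approx(ref.loc["ICC(A,k)", "ICC"], abs=1e-6)
        assert p == pytest.approx(ref.loc["ICC(A,k)", "pval"], abs=1e-6)

    def test_na_rows_dropped_listwise(self):
        m = np.array(
            [[1, 1], [2, 2], [3, 3], [0, 2], [1, 0.5], [2, 2]], dtype=float
        )
        icc, _ = icc_2k(m)
        kept = np.array([[1, 1], [2, 2], [3, 3], [2, 2]], dtype=float)
        assert icc == pytest.approx(icc_2k(kept)[0])


class TestDice:
    def test_identical_vectors_all_one(self):
        v = ["na", "improve", "no_change", "worse", "improve"]
        assert all(x == 1.0 for x in dice_per_category(v, v).values())

    def test_hand_counted_overlap(self):
        # 3 N/A per rater, 2 at shared positions: 2*2/(3+3)
        r1 = ["na", "na", "na", "improve", "improve", "worse"]
        r2 = ["na", "na", "improve", "na", "improve", "worse"]
        assert dice_per_category(r1, r2)["na"] == pytest.approx(2 * 2 / 6)

    def test_one_sided_category_zero(self):
        r1 = ["improve", "improve"]
        r2 = ["worse", "improve"]
        assert dice_per_category(r1, r2)["worse"] == 0.0

    def test_symmetric_in_raters(self):
        r1 = ["na", "improve", "worse", "no_change"]
        r2 = ["improve", "improve", "worse", "na"]
        assert dice_per_category(r1, r2) == dice_per_category(r2, r1)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            dice_per_category(["a"], ["a", "b"])


class TestSpearman:
    def test_perfect_monotone(self):
        rho, _ = spearman_rho([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)

    def test_matches_rank_oracle_with_ties(self):
        x = [1, 2, 2, 3, 1, 3, 2, 1, 3, 2]
        y = [4, 5, 6, 7, 4, 6, 6, 5, 7, 5]
        rho, _ = spearman_rho(x, y)
        rx, ry = sps.rankdata(x), sps.rankdata(y)  # midranks
        oracle = np.corrcoef(rx, ry)[0, 1]  # Pearson on ranks
        assert rho == pytest.approx(oracle, abs=1e-9)

    def test_constant_vector_error(self):
        with pytest.raises(DegenerateStatisticError):
            spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])


class TestBootstrapBca:
    def test_ci_brackets_mean(self):
        sample = np.arange(1, 101, dtype=float)
        res = bootstrap_ci_bca(np.mean, sample, n_resamples=500, seed=0)
        assert res.lower < 50.5 < res.upper
        assert res.lower <= res.point <= res.upper

    def test_degenerate_sample_zero_width(self):
        res = bootstrap_ci_bca(np.mean, np.full(10, 3.0), n_resamples=200, seed=0)
        assert (res.point, res.lower, res.upper) == (3.0, 3.0, 3.0)

    def test_deterministic_given_seed(self):
        sample = np.random.default_rng(1).normal(size=40)
        a = bootstrap_ci_bca(np.median, sample, n_resamples=500, seed=42)
        b = bootstrap_ci_bca(np.median, sample, n_resamples=500, seed=42)
        assert json.dumps(a.as_tuple()) == json.dumps(b.as_tuple())
        c = bootstrap_ci_bca(np.median, sample, n_resamples=500, seed=43)
        assert a.as_tuple() != c.as_tuple()

    def test_reduces_to_percentile_when_corrections_vanish(self):
        sample = np.random.default_rng(2).normal(size=60)
        res = bootstrap_ci_bca(np.mean, sample, n_resamples=1000, seed=3)
        lo, hi = _bca_interval(res.distribution, z0=0.0, acceleration=0.0)
        assert lo == pytest.approx(np.quantile(res.distribution, 0.025))
        assert hi == pytest.approx(np.quantile(res.distribution, 0.975))
        # symmetric statistic: the BCa interval sits close to percentile
        assert res.lower == pytest.approx(lo, abs=0.05)
        assert res.upper == pytest.approx(hi, abs=0.05)

    def test_close_to_scipy_bca(self):
        sample = np.random.default_rng(4).normal(size=50)
        res = bootstrap_ci_bca(np.mean, sample, n_resamples=2000, seed=5)
        ref = sps.bootstrap(
            (sample,), np.mean, n_resamples=2000, method="BCa",
            random_state=np.random.default_rng(5),
        )
        assert res.lower == pytest.approx(ref.confidence_interval.low, abs=0.05)
        assert res.upper == pytest.approx(ref.confidence_interval.high, abs=0.05)

    def test_mostly_undefined_statistic_fails(self):
        def fussy(s):
            if len(set(s.tolist())) < len(s):
                raise ValueError("needs all-distinct values")
            return float(np.mean(s))

        with pytest.raises(DegenerateStatisticError, match="undefined"):
            bootstrap_ci_bca(fussy, np.arange(5.0), n_resamples=200, seed=0)


def mnlogit_loglik_oracle(y, x):
    """Brute-force MLE of a 3-category baseline logit with one binary
    covariate, via direct likelihood maximisation."""
    from scipy.optimize import minimize

    y = np.asarray(y)
    x = np.asarray(x, dtype=float)

    def negll(theta):
        a1, b1, a2, b2 = theta
        eta = np.stack([np.zeros_like(x), a1 + b1 * x, a2 + b2 * x], axis=1)
        logz = np.log(np.exp(eta).sum(axis=1))
        return -(eta[np.arange(y.size), y] - logz).sum()

    best = min(
        (minimize(negll, start, method="Nelder-Mead",
                  options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
         for start in ([0.0] * 4, [0.5, -0.5, -0.5, 0.5])),
        key=lambda r: r.fun,
    )
    return -best.fun


class TestMultinomialLogit:
    def test_loglik_matches_bruteforce_mle(self):
        rng = np.random.default_rng(8)
        x = rng.integers(0, 2, size=120)
        probs = np.where(x[:, None] == 1, [0.2, 0.5, 0.3], [0.4, 0.3, 0.3])
        y = np.array([rng.choice(3, p=p) for p in probs])
        labels = np.array(["responder", "non_responder", "intolerant"])[y]
        _, details = fit_multinomial_logit(
            labels, pd.DataFrame({"sex": x}), return_details=True
        )
        assert details["llf"] == pytest.approx(
            mnlogit_loglik_oracle(y, x), abs=1e-6
        )

    def test_null_covariate_rarely_significant(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n = 2000
            y = rng.choice(["responder", "non_responder", "intolerant"],
                           size=n, p=[0.6, 0.3, 0.1])
            cov = pd.DataFrame({
                "sex": rng.choice(["woman", "man"], size=n),
                "age": rng.normal(74, 9, size=n),
            })
            p = fit_multinomial_logit(y, cov)
            hits += (p["sex"] > 0.05) and (p["age"] > 0.05)
        assert hits >= 9

    def test_near_deterministic_covariate_floor_p(self):
        rng = np.random.default_rng(9)
        n = 400
        sex = rng.choice(["woman", "man"], size=n)
        y = np.where(sex == "woman", "responder", "non_responder").copy()
        flip = rng.random(n) < 0.05  # keep the MLE finite
        y[flip] = np.where(y[flip] == "responder", "non_responder", "responder")
        p = fit_multinomial_logit(y, pd.DataFrame({"sex": sex}))
        assert p["sex"] < 1e-10

    def test_single_outcome_category_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_multinomial_logit(
                ["responder"] * 10, pd.DataFrame({"sex": ["man"] * 10})
            )


class TestRateTable:
    def make(self, categories, drug_class="SSRI"):
        note_of = {"responder": 1.0, "non_responder": 2.0,
                   "intolerant": 0.5, "not_evaluable": 0.0}
        cls, scores = [], []
        domain = "psychiatric" if drug_class == "SSRI" else "cognitive"
        for i, cat in enumerate(categories):
            eid = f"E{i}"
            cls.append(ResponderClassification(eid, drug_class, cat))
            note = note_of[cat]
            cibic = {1.0: 0, 2.0: 4, 0.5: 0.5, 0.0: 0.0}[note]
            scores.append(EpisodeScore(eid, domain, note, cibic))
        return cls, scores

    def test_three_of_four_is_75_percent(self):
        cls, scores = self.make(
            ["responder", "responder", "responder", "non_responder"]
        )
        table = responder_rate_table(cls, scores)
        resp = table["SSRI"]["responders"]
        assert resp.loc["responder", "count"] == 3
        assert resp.loc["responder", "percent"] == 75.0

    def test_percent_sums_to_100_within_rounding(self):
        cls, scores = self.make(
            ["responder"] * 7 + ["non_responder"] * 3 + ["intolerant"] * 2
            + ["not_evaluable"]
        )
        table = responder_rate_table(cls, scores)
        total_pct = table["SSRI"]["note_categories"]["percent"].sum()
        assert total_pct == pytest.approx(100.0, abs=0.3)

    def test_empty_input_all_zero(self):
        table = responder_rate_table([], [])
        assert table == {}

    def test_stratified_counts(self):
        cls, scores = self.make(["responder", "non_responder", "responder"])
        cov = pd.DataFrame(
            {"diagnosis_group": ["AD", "AD", "VD"],
             "sex": ["woman", "man", "woman"],
             "age": [70, 80, 75]},
            index=["E0", "E1", "E2"],
        )
        table = responder_rate_table(cls, scores, cov)
        ad = table["SSRI"]["diagnosis_group"]["AD"]
        assert int(ad["count"].sum()) == 2
        mean, sd = table["SSRI"]["age_overall"]
        assert mean == pytest.approx(75.0)


class TestRounding:
    @pytest.mark.parametrize(
        "value,expected",
        [(69.333, 69.3), (7.555, 7.6), (2.666, 2.7), (0.05, 0.1), (12.25, 12.3)],
    )
    def test_half_up_one_decimal(self, value, expected):
        assert round_half_up(value, 1) == expected
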