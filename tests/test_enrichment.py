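"""Logistic enrichment model: likelihood oracle, BH, recovery, reports."""
import math

import numpy as np
import pytest
from scipy import optimize, special

from scoremea.covariates import CovariateTable, KIND_USER
from scoremea.enrichment import (
    STATUS_OK,
    STATUS_SEPARATION,
    bh_adjust,
    covariate_effect_report,
    enrich_all,
    fit_motif_logit,
    results_to_frame,
)
from scoremea.motifs import MotifMatrix
from scoremea.scanner import PresenceMatrix
from scoremea.seqio import ScoredSequence
from scoremea.simulate import PlantedMotif, SimulationSpec, simulate_scored_sequences


def loglike_oracle_fit(y, X):
    """Independent maximizer of the logistic log-likelihood (BFGS on the
    hand-written objective), used to cross-check the model fit."""

    def negll(beta):
        eta = X @ beta
        return -(y * eta - np.logaddexp(0.0, eta)).sum()

    res = optimize.minimize(
        negll, np.zeros(X.shape[1]), method="BFGS",
        options={"gtol": 1e-10, "maxiter": 500},
    )
    return res.x


class TestFitMotifLogit:
    def test_symmetric_design_gives_zero_coefficient(self):
        model = fit_motif_logit(np.array([1, 0, 1, 0]), np.array([-1.0, -1.0, 1.0, 1.0]))
        assert model.score_coefficient == pytest.approx(0.0, abs=1e-10)
        assert model.score_wald_p == pytest.approx(1.0, abs=1e-10)

    def test_matches_likelihood_oracle(self, rng):
        for _ in range(5):
            n = 300
            x = rng.standard_normal(n)
            z = rng.standard_normal((n, 2))
            eta = -0.5 + 0.8 * x + 0.3 * z[:, 0]
            y = rng.random(n) < special.expit(eta)
            model = fit_motif_logit(y, x, z)
            assert model.status == STATUS_OK
            X = np.column_stack([np.ones(n), x, z])
            oracle = loglike_oracle_fit(y.astype(float), X)
            assert model.intercept == pytest.approx(oracle[0], abs=1e-4)
            assert model.score_coefficient == pytest.approx(oracle[1], abs=1e-4)
            np.testing.assert_allclose(model.covariate_coefficients, oracle[2:], atol=1e-4)

    def test_sign_flip_antisymmetry(self, rng):
        n = 200
        x = rng.standard_normal(n)
        y = rng.random(n) < special.expit(-1 + x)
        a = fit_motif_logit(y, x)
        b = fit_motif_logit(y, -x)
        assert a.score_coefficient == pytest.approx(-b.score_coefficient, abs=1e-8)
        assert a.score_wald_p == pytest.approx(b.score_wald_p, abs=1e-10)

    def test_all_same_presence_is_separation(self):
        x = np.array([-1.0, 0.0, 1.0])
        for y in ([1, 1, 1], [0, 0, 0]):
            model = fit_motif_logit(np.array(y), x)
            assert model.status == STATUS_SEPARATION
            assert not model.converged

    def test_perfectly_separated_predictor_flagged(self):
        x = np.linspace(-2, 2, 40)
        y = (x > 0).astype(float)
        model = fit_motif_logit(y, x)
        assert model.status == STATUS_SEPARATION


class TestBH:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), [0.04, 0.04, 0.04, 0.04]
        )

    def test_matches_step_up_oracle(self, rng):
        p = rng.random(25)
        adjusted = bh_adjust(p)
        m = p.size
        order = np.argsort(p)
        oracle = np.empty(m)
        running = 1.0
        for rank_from_top in range(m, 0, -1):
            i = order[rank_from_top - 1]
            running = min(running, p[i] * m / rank_from_top)
            oracle[i] = running
        np.testing.assert_allclose(adjusted, oracle, atol=1e-12)

    def test_monotone_in_rank(self, rng):
        p = rng.random(40)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


def _presence_matrix(names, motif_presences):
    present = np.column_stack(list(motif_presences.values()))
    return PresenceMatrix(
        list(names), list(motif_presences.keys()), present.astype(bool),
        present.astype(np.int64),
    )


class TestEnrichAll:
    def _dataset(self, rng, n=400, betas=(1.0, 0.0)):
        scores = rng.standard_normal(n)
        z = (scores - scores.mean()) / scores.std(ddof=1)
        seqs = [ScoredSequence(f"s{i}", "", float(scores[i])) for i in range(n)]
        presences = {
            f"M{j}": rng.random(n) < special.expit(-1 + b * z)
            for j, b in enumerate(betas)
        }
        return seqs, _presence_matrix([s.name for s in seqs], presences)

    def test_single_motif_adjusted_equals_raw(self, rng):
        seqs, pm = self._dataset(rng, betas=(0.8,))
        [res] = enrich_all(pm, seqs)
        assert res.adjusted_p == pytest.approx(res.wald_p)

    def test_sort_modes_and_tie_break(self, rng):
        seqs, pm = self._dataset(rng, betas=(1.0, -1.5, 0.0))
        by_coef = enrich_all(pm, seqs, sort_mode="coef")
        coefs = [r.coefficient for r in by_coef]
        assert coefs == sorted(coefs, reverse=True)
        by_abs = enrich_all(pm, seqs, sort_mode="abs")
        mags = [abs(r.coefficient) for r in by_abs]
        assert mags == sorted(mags, reverse=True)

    def test_failed_fits_sorted_last_and_excluded_from_bh(self, rng):
        seqs, pm = self._dataset(rng, betas=(1.0, 0.0))
        pm.present[:, 1] = True  # all-present motif cannot be fitted
        results = enrich_all(pm, seqs)
        assert results[-1].status == STATUS_SEPARATION
        assert math.isnan(results[-1].adjusted_p)
        ok = [r for r in results if r.status == STATUS_OK]
        assert len(ok) == 1 and ok[0].adjusted_p == pytest.approx(ok[0].wald_p)

    def test_planted_effect_recovery(self):
        motif = MotifMatrix.from_consensus("PLANT", "ATGCGTCAAC")
        spec = SimulationSpec(
            n_sequences=2000, length=200, seed=11,
            planted=[PlantedMotif(motif, beta_score=1.0)],
        )
        seqs, truth = simulate_scored_sequences(spec)
        pm = _presence_matrix(
            [s.name for s in seqs], {"PLANT": truth["present_PLANT"].to_numpy()}
        )
        [res] = enrich_all(pm, seqs)
        assert res.coefficient == pytest.approx(1.0, abs=0.2)
        assert res.adjusted_p < 0.05

    def test_pure_noise_covariate_barely_moves_coefficient(self, rng):
        seqs, pm = self._dataset(rng, n=1000, betas=(1.0,))
        [plain] = enrich_all(pm, seqs)
        noise = rng.standard_normal(1000)
        table = CovariateTable(
            [s.name for s in seqs], ["noise"], noise[:, None], [KIND_USER]
        )
        [with_noise] = enrich_all(pm, seqs, table)
        assert abs(with_noise.coefficient - plain.coefficient) < 2 * plain.std_err

    def test_results_frame_layout(self, rng):
        seqs, pm = self._dataset(rng)
        frame = results_to_frame(enrich_all(pm, seqs))
        assert list(frame.columns) == [
            "motif_id", "motif_name", "coefficient", "std_err", "wald_p",
            "adjusted_p", "n_present", "n_total", "status",
        ]


class TestCovariateEffectReport:
    def test_zero_covariates_gives_empty_table(self, rng):
        n = 100
        x = rng.standard_normal(n)
        y = rng.random(n) < 0.4
        model = fit_motif_logit(y, x)
        assert len(covariate_effect_report(model)) == 0

    def test_gc_effect_recovery(self, rng):
        # presence depends only on GC: logit = -1 * GC_std
        n = 2000
        gc = rng.normal(0.5, 0.1, n)
        gc_std = (gc - gc.mean()) / gc.std(ddof=1)
        y = rng.random(n) < special.expit(-gc_std)
        score = rng.standard_normal(n)
        model = fit_motif_logit(y, score, gc_std[:, None], ["GC"])
        report = covariate_effect_report(model)
        assert report.loc[0, "column"] == "GC"
        assert report.loc[0, "coefficient"] == pytest.approx(-1.0, abs=0.15)
        assert report.loc[0, "wald_p"] < 0.01

    def test_column_order_preserved(self, rng):
        n = 300
        x = rng.standard_normal(n)
        z = rng.standard_normal((n, 3))
        y = rng.random(n) < 0.4
        model = fit_motif_logit(y, x, z, ["a", "b", "c"])
        assert list(covariate_effect_report(model)["column"]) == ["a", "b", "c"]
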