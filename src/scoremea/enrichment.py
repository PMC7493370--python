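"""Per-motif logistic regression of presence on sequence score.

For each motif m, with p the probability of a sequence containing m, the
model is

    log(p / (1 - p)) = beta_0 + beta_s * x_s + sum_c beta_c * x_c

where x_s is the (standardized) sequence activity score and the x_c are the
(standardized) reduced composition covariates plus any user covariates.
beta_s is the change in the log-odds of containing the motif per one
standard deviation of score: positive means the motif concentrates in
high-scoring sequences.  Significance of beta_s is a two-sided Wald test;
Benjamini-Hochberg correction is applied across motifs.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm_api
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .covariates import CovariateTable, standardize_columns
from .scanner import PresenceMatrix
from .seqio import ScoredSequence

STATUS_OK = "ok"
STATUS_SEPARATION = "separation"
STATUS_NONCONVERGENCE = "nonconvergence"

#: |coefficient| beyond this on the standardized scale is treated as
#: quasi-separation (the MLE is diverging)
SEPARATION_COEF_LIMIT = 15.0

MAX_ITER = 100
TOL = 1e-8


@dataclass
class LogitModel:
    """A fitted per-motif logistic regression (or the reason it failed)."""

    intercept: float
    score_coefficient: float
    covariate_coefficients: np.ndarray
    standard_errors: np.ndarray  # (intercept, score, covariates...)
    pvalues: np.ndarray          # same layout, two-sided Wald
    converged: bool
    status: str = STATUS_OK
    column_names: list[str] = field(default_factory=list)

    @property
    def score_std_err(self) -> float:
        return float(self.standard_errors[1])

    @property
    def score_wald_p(self) -> float:
        return float(self.pvalues[1])


@dataclass
class EnrichmentResult:
    motif_id: str
    motif_name: str
    coefficient: float
    std_err: float
    wald_p: float
    adjusted_p: float
    n_present: int
    n_total: int
    status: str


def fit_motif_logit(
    presence: np.ndarray,
    scores: np.ndarray,
    covariates: np.ndarray | None = None,
    column_names: Sequence[str] | None = None,
) -> LogitModel:
    """Maximum-likelihood logistic fit of presence on score (+ covariates).

    Predictors are expected already standardized.  Newton iterations, at most
    100, convergence tolerance 1e-8; standard errors from the inverse
    observed information; p-values are two-sided normal Wald tests.
    All-true/all-false presence or a diverging fit is flagged as separation
    rather than fitted.
    """
    y = np.asarray(presence, dtype=float)
    x_s = np.asarray(scores, dtype=float)
    if covariates is None:
        covariates = np.zeros((y.size, 0))
    covariates = np.asarray(covariates, dtype=float)
    if covariates.ndim == 1:
        covariates = covariates[:, None]
    if not (y.size == x_s.size == covariates.shape[0]):
        raise ValueError("presence, scores and covariates must have equal lengths")
    n_cov = covariates.shape[1]
    names = list(column_names) if column_names is not None else [
        f"cov{i + 1}" for i in range(n_cov)
    ]

    def failed(status: str) -> LogitModel:
        k = n_cov + 2
        nan = np.full(k, math.nan)
        return LogitModel(
            math.nan, math.nan, np.full(n_cov, math.nan), nan, nan.copy(),
            False, status, names,
        )

    if y.min() == y.max():
        return failed(STATUS_SEPARATION)
    X = np.column_stack([np.ones_like(x_s), x_s, covariates])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm_api.Logit(y, X).fit(
                method="newton", maxiter=MAX_ITER, tol=TOL, disp=0, warn_convergence=False
            )
        except (PerfectSeparationError, np.linalg.LinAlgError):
            return failed(STATUS_SEPARATION)
    params = np.asarray(res.params)
    if not np.isfinite(params).all() or np.abs(params).max() > SEPARATION_COEF_LIMIT:
        return failed(STATUS_SEPARATION)
    if not res.mle_retvals.get("converged", False):
        return failed(STATUS_NONCONVERGENCE)
    return LogitModel(
        float(params[0]),
        float(params[1]),
        params[2:].copy(),
        np.asarray(res.bse),
        np.asarray(res.pvalues),
        True,
        STATUS_OK,
        names,
    )


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues.copy()
    return multipletests(pvalues, method="fdr_bh")[1]


def enrich_all(
    presence_matrix: PresenceMatrix,
    scored_sequences: Sequence[ScoredSequence],
    covariate_table: CovariateTable | None = None,
    sort_mode: str = "coef",
    motif_names: dict[str, str] | None = None,
) -> list[EnrichmentResult]:
    """Fit the enrichment model for every motif and BH-correct across motifs.

    The score and all covariate columns are standardized jointly before
    fitting, so coefficients are on the standardized-predictor scale.  BH
    adjustment runs over motifs with a successful fit only.  ``sort_mode``
    is ``"coef"`` (coefficient descending) or ``"abs"`` (|coefficient|
    descending); ties break by motif id.
    """
    if sort_mode not in ("coef", "abs"):
        raise ValueError(f"sort_mode must be 'coef' or 'abs', got {sort_mode!r}")
    names = [s.name for s in scored_sequences]
    if names != presence_matrix.sequence_names:
        raise ValueError("sequence order mismatch between presence matrix and sequences")
    scores = np.array([s.score for s in scored_sequences], dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("sequence scores must be finite")
    if covariate_table is not None and covariate_table.sequence_names != names:
        raise ValueError("sequence order mismatch between covariates and sequences")

    cov_vals = (
        covariate_table.values if covariate_table is not None else np.zeros((len(names), 0))
    )
    cov_names = list(covariate_table.column_names) if covariate_table is not None else []
    design = np.column_stack([scores, cov_vals])
    design_std, kept = standardize_columns(design, ["score"] + cov_names)
    if 0 not in kept:
        raise ValueError("sequence scores have zero variance; enrichment is undefined")
    x_s = design_std[:, kept.index(0)]
    cov_cols = [i for i in range(len(kept)) if kept[i] != 0]
    cov_std = design_std[:, cov_cols]
    kept_cov_names = [(["score"] + cov_names)[kept[i]] for i in cov_cols]

    motif_names = motif_names or {}
    results: list[EnrichmentResult] = []
    for j, motif_id in enumerate(presence_matrix.motif_ids):
        y = presence_matrix.present[:, j]
        model = fit_motif_logit(y, x_s, cov_std, kept_cov_names)
        results.append(
            EnrichmentResult(
                motif_id=motif_id,
                motif_name=motif_names.get(motif_id, motif_id),
                coefficient=model.score_coefficient,
                std_err=model.score_std_err if model.converged else math.nan,
                wald_p=model.score_wald_p if model.converged else math.nan,
                adjusted_p=math.nan,
                n_present=int(y.sum()),
                n_total=int(y.size),
                status=model.status,
            )
        )
    ok = [r for r in results if r.status == STATUS_OK]
    if ok:
        adjusted = bh_adjust(np.array([r.wald_p for r in ok]))
        for r, ap in zip(ok, adjusted):
            r.adjusted_p = float(ap)

    if sort_mode == "abs":
        key = lambda r: (-(abs(r.coefficient) if r.status == STATUS_OK else -math.inf), r.motif_id)
    else:
        key = lambda r: (-(r.coefficient if r.status == STATUS_OK else -math.inf), r.motif_id)
    results.sort(key=key)
    return results


def covariate_effect_report(
    model: LogitModel, column_names: Sequence[str] | None = None
) -> pd.DataFrame:
    """Coefficient and two-sided Wald p for every covariate of a fitted model.

    Enables composition-only analyses (e.g. fitting with single-nucleotide
    covariates and reading off the GC coefficient directly).
    """
    if not model.converged:
        raise ValueError("covariate effects require a converged model")
    names = list(column_names) if column_names is not None else model.column_names
    n_cov = model.covariate_coefficients.size
    if len(names) != n_cov:
        raise ValueError(f"expected {n_cov} column names, got {len(names)}")
    return pd.DataFrame(
        {
            "column": names,
            "coefficient": model.covariate_coefficients,
            "wald_p": model.pvalues[2:],
        }
    )


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Enrichment results as the output TSV layout."""
    return pd.DataFrame(
        [
            (
                r.motif_id, r.motif_name, r.coefficient, r.std_err,
                r.wald_p, r.adjusted_p, r.n_present, r.n_total, r.status,
            )
            for r in results
        ],
        columns=[
            "motif_id", "motif_name", "coefficient", "std_err",
            "wald_p", "adjusted_p", "n_present", "n_total", "status",
        ],
    )
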