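"""Per-gene factorial dose modelling and backward model simplification.

Each gene's counts are modelled with a negative-binomial log-link GLM on
four standardized dose predictors,

    log E[count] = log(size factor) + alpha
                   + b_N * N + b_W * W + b_NdivW * N/W + b_NxW * NxW,

and the model is then simplified by backward elimination: the least
significant term (largest FDR-adjusted Wald p across genes) is dropped and
the reduced model refit, until every surviving term passes the FDR
threshold.  A gene ends up assigned to the full model, to one of the 14
reduced term subsets, or to no model at all ("unclassified", excluded
downstream).  The relative weight of the N-moles versus N-molarity
coefficients quantifies, for genes fit by N and/or N/W, whether expression
tracks the amount of nitrogen or its concentration.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.stats import nbinom
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .core_io import (
    TERMS,
    TERM_COLUMNS,
    AnalysisConfig,
    CountMatrix,
    TreatmentDesign,
    filter_low_counts,
)

__all__ = [
    "GeneModelFit",
    "size_factors",
    "enumerate_model_forms",
    "fit_full_model",
    "simplify_models",
    "classify_genes",
    "compute_nw_weights",
    "fits_table",
]

_MIN_DISPERSION = 1e-8
_MAX_DISPERSION = 50.0


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios per-sample normalization factors.

    For each sample, the factor is the median over genes (restricted to
    genes with a strictly positive geometric mean across samples) of the
    ratio of the gene's count in that sample to its geometric mean.
    """
    values = counts.values().astype(float)
    zero_samples = [s for s, tot in zip(counts.sample_ids, values.sum(axis=0))
                    if tot == 0]
    if zero_samples:
        raise ValueError(f"samples with all-zero counts: {zero_samples}")
    with np.errstate(divide="ignore"):
        log_counts = np.log(values)
    log_geomean = log_counts.mean(axis=1)
    usable = np.isfinite(log_geomean)
    if not usable.any():
        raise ValueError("no gene has positive counts in every sample; "
                         "size factors are undefined")
    ratios = np.exp(log_counts[usable] - log_geomean[usable, None])
    factors = np.median(ratios, axis=0)
    if (factors <= 0).any():
        bad = [s for s, f in zip(counts.sample_ids, factors) if f <= 0]
        raise ValueError(f"non-positive size factor for samples: {bad}")
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


# ---------------------------------------------------------------------------
# Model forms
# ---------------------------------------------------------------------------


def enumerate_model_forms() -> list[tuple[str, ...]]:
    """All 14 reduced model forms: non-empty proper subsets of the 4 terms,
    largest subsets first, ties broken by term order (N, W, N/W, NxW)."""
    forms = []
    for size in (3, 2, 1):
        forms.extend(itertools.combinations(TERMS, size))
    return forms


def class_label(terms: Sequence[str]) -> str:
    """Canonical class label for a term subset ('N+NdivW' style)."""
    ordered = [t for t in TERMS if t in terms]
    if len(ordered) != len(set(terms)):
        raise ValueError(f"unknown terms in {terms!r}")
    return "+".join(ordered)


# ---------------------------------------------------------------------------
# Per-gene negative-binomial fits
# ---------------------------------------------------------------------------


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    size = 1.0 / phi
    return float(nbinom.logpmf(y, size, size / (size + mu)).sum())


def estimate_dispersion(y: np.ndarray, mu: np.ndarray,
                        X: np.ndarray | None = None) -> float:
    """Maximum-likelihood NB dispersion given fitted means.

    Method-of-moments start, profile likelihood maximized on the log scale,
    floored at 1e-8.  When the design matrix ``X`` is supplied the
    Cox-Reid adjustment (-0.5 log det X'WX) corrects the downward bias from
    estimating the mean parameters on the same data.  No shrinkage across
    genes is applied.
    """
    def objective(log_phi: float) -> float:
        phi = np.exp(log_phi)
        ll = _nb_loglik(y, mu, phi)
        if X is not None:
            w = mu / (1.0 + phi * mu)
            sign, logdet = np.linalg.slogdet(X.T @ (X * w[:, None]))
            if sign > 0:
                ll -= 0.5 * logdet
        return -ll

    mom = float(((y - mu) ** 2 - mu).sum() / (mu ** 2).sum())
    mom = min(max(mom, _MIN_DISPERSION), _MAX_DISPERSION)
    res = minimize_scalar(
        objective,
        bounds=(np.log(_MIN_DISPERSION), np.log(_MAX_DISPERSION)),
        method="bounded", options={"xatol": 1e-3})
    phi = float(np.exp(res.x))
    # keep whichever of {adjusted MLE, MoM start} scores better; the bounded
    # search can stall at an edge for near-Poisson genes
    if objective(np.log(mom)) < objective(np.log(phi)):
        phi = mom
    return max(phi, _MIN_DISPERSION)


def _fit_nb_glm(y: np.ndarray, X: np.ndarray, offset: np.ndarray,
                phi: float | None = None):
    """Fit an NB log-link GLM; estimates dispersion if not supplied.

    Returns (params, pvalues, phi, ok).  Wald z-tests give the per-term
    p-values.  Any numerical failure returns ok=False.
    """
    try:
        if phi is None:
            pois = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset)
            mu = pois.fit().mu
            phi = estimate_dispersion(y, mu, X)
        model = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=phi),
                       offset=offset)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit()
        if not np.all(np.isfinite(res.params)) or not np.all(np.isfinite(res.bse)):
            return None, None, phi, False
        return res.params, res.pvalues, phi, True
    except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
        return None, None, phi if phi is not None else np.nan, False


@dataclass
class GeneModelFit:
    """Fit state and final classification for one gene.

    Coefficients and p-values refer to the accepting model stage (the full
    model for unclassified genes).  ``trace`` records one entry per
    elimination stage: the term subset, adjusted p-values and the dropped
    term, so backward-elimination soundness can be audited directly.
    """

    gene_id: str
    terms: tuple[str, ...]
    coefficients: dict[str, float] = field(default_factory=dict)  # incl. intercept
    raw_p: dict[str, float] = field(default_factory=dict)
    adj_p: dict[str, float] = field(default_factory=dict)
    dispersion: float = np.nan
    model_class: str = "unclassified"
    converged: bool = True
    diagnostic: str = ""
    trace: list[dict] = field(default_factory=list)


def _design_matrix(design: TreatmentDesign, terms: Sequence[str]) -> np.ndarray:
    pred = design.predictors()
    cols = [np.ones(design.n_samples)]
    cols += [pred[TERM_COLUMNS[t]].to_numpy() for t in terms]
    return np.column_stack(cols)


def fit_full_model(
    counts: CountMatrix,
    design: TreatmentDesign,
    config: AnalysisConfig,
    factors: pd.Series | None = None,
) -> list[GeneModelFit]:
    """Fit the four-term NB GLM to every gene; BH-adjust per term across genes.

    ``counts`` should already have passed :func:`filter_low_counts`.  Genes
    whose fit fails numerically are flagged unclassified with a diagnostic,
    never dropped silently.
    """
    counts.check_matches_design(design)
    if factors is None:
        factors = size_factors(counts)
    offset = np.log(factors.to_numpy())
    X = _design_matrix(design, TERMS)
    values = counts.values()

    fits: list[GeneModelFit] = []
    for g, gene_id in enumerate(counts.gene_ids):
        params, pvals, phi, ok = _fit_nb_glm(values[g], X, offset)
        fit = GeneModelFit(gene_id, TERMS, dispersion=phi)
        if ok:
            fit.coefficients = {"intercept": params[0],
                                **{t: params[i + 1] for i, t in enumerate(TERMS)}}
            fit.raw_p = {t: pvals[i + 1] for i, t in enumerate(TERMS)}
        else:
            fit.converged = False
            fit.diagnostic = "full-model fit failed"
        fits.append(fit)

    _adjust_per_term(fits)
    return fits


def _adjust_per_term(fits: Sequence[GeneModelFit]) -> None:
    """BH-adjust raw p-values per term, across the genes carrying that term."""
    for term in TERMS:
        carriers = [f for f in fits
                    if f.converged and term in f.terms and term in f.raw_p]
        if not carriers:
            continue
        raw = np.asarray([f.raw_p[term] for f in carriers])
        adj = multipletests(raw, method="fdr_bh")[1]
        for f, p in zip(carriers, adj):
            f.adj_p[term] = float(p)


def simplify_models(
    fits: Sequence[GeneModelFit],
    refit: Callable[[str, tuple[str, ...]], tuple[dict, dict, bool]],
    config: AnalysisConfig,
) -> None:
    """Backward elimination over all genes, in place.

    Stage k (k = 4, 3, 2, 1): every still-active gene holds a k-term model
    with BH-adjusted per-term p-values (adjustment per term across the genes
    at that stage).  A gene is accepted iff every term passes
    ``model_alpha`` (class "full" at k = 4, otherwise its term subset);
    otherwise the term with the largest adjusted p is dropped (ties broken
    toward the later term in the fixed N, W, N/W, NxW order) and the reduced
    model is refit.  Genes surviving no stage become "unclassified".

    ``refit(gene_id, terms)`` must return ``(coefficients, raw_p, ok)`` for
    the reduced model, with coefficients keyed by "intercept" and term name.
    """
    active = [f for f in fits if f.converged]
    for f in fits:
        if not f.converged:
            f.model_class = "unclassified"

    for stage_size in (4, 3, 2, 1):
        if not active:
            break
        _adjust_per_term(active)
        survivors = []
        for f in active:
            stage = {"terms": f.terms,
                     "adj_p": {t: f.adj_p[t] for t in f.terms}}
            if all(f.adj_p[t] < config.model_alpha for t in f.terms):
                f.model_class = "full" if stage_size == 4 else class_label(f.terms)
                stage["accepted"] = True
                f.trace.append(stage)
                continue
            stage["accepted"] = False
            if stage_size == 1:
                f.model_class = "unclassified"
                f.diagnostic = f.diagnostic or "no model form passed"
                f.trace.append(stage)
                continue
            # drop the least significant term; tie-break toward the later
            # term in the fixed order (deterministic)
            worst = max(f.terms, key=lambda t: (f.adj_p[t], TERMS.index(t)))
            stage["dropped"] = worst
            f.trace.append(stage)
            reduced = tuple(t for t in f.terms if t != worst)
            coefs, raw_p, ok = refit(f.gene_id, reduced)
            if not ok:
                f.model_class = "unclassified"
                f.converged = False
                f.diagnostic = f"refit failed at {class_label(reduced)}"
                continue
            f.terms, f.coefficients, f.raw_p, f.adj_p = reduced, coefs, raw_p, {}
            survivors.append(f)
        active = survivors


def classify_genes(
    counts: CountMatrix,
    design: TreatmentDesign,
    config: AnalysisConfig | None = None,
    prefiltered: bool = False,
) -> list[GeneModelFit]:
    """Full lab-side classification pipeline.

    Filters low-count genes, computes size factors, fits the full four-term
    model and runs backward elimination.  Returns one :class:`GeneModelFit`
    per retained gene; N-vs-N/W weights are attached by :func:`fits_table`.
    """
    config = config or AnalysisConfig()
    if not prefiltered:
        counts = filter_low_counts(counts, config)
    factors = size_factors(counts)
    offset = np.log(factors.to_numpy())
    values = counts.values()
    row_of = {g: i for i, g in enumerate(counts.gene_ids)}

    fits = fit_full_model(counts, design, config, factors)
    phi_of = {f.gene_id: f.dispersion for f in fits}

    def refit(gene_id: str, terms: tuple[str, ...]):
        X = _design_matrix(design, terms)
        params, pvals, _, ok = _fit_nb_glm(
            values[row_of[gene_id]], X, offset, phi=phi_of[gene_id])
        if not ok:
            return {}, {}, False
        coefs = {"intercept": params[0],
                 **{t: params[i + 1] for i, t in enumerate(terms)}}
        raw_p = {t: pvals[i + 1] for i, t in enumerate(terms)}
        return coefs, raw_p, True

    simplify_models(fits, refit, config)
    return fits


# ---------------------------------------------------------------------------
# N-moles vs N-molarity weights
# ---------------------------------------------------------------------------

_WEIGHT_CLASSES = {"N", "NdivW", "N+NdivW"}


def compute_nw_weights(fit: GeneModelFit) -> tuple[float, float]:
    """Percentage weight of the N-moles vs N-molarity coefficients.

    Defined for genes classified as N, N/W, or N + N/W:
    ``n_weight = 100 * |b_N| / (|b_N| + |b_NdivW|)`` with an absent term
    contributing 0, and ``ndivw_weight = 100 - n_weight``.  A pure-N gene
    therefore scores (100, 0).
    """
    if fit.model_class not in _WEIGHT_CLASSES:
        raise ValueError(
            f"{fit.gene_id}: weights defined only for classes "
            f"{sorted(_WEIGHT_CLASSES)}, not {fit.model_class!r}")
    b_n = abs(fit.coefficients.get("N", 0.0))
    b_ndivw = abs(fit.coefficients.get("NdivW", 0.0))
    total = b_n + b_ndivw
    if total == 0:
        raise ValueError(f"{fit.gene_id}: both coefficients are zero")
    n_weight = 100.0 * b_n / total
    return n_weight, 100.0 - n_weight


def fits_table(fits: Sequence[GeneModelFit]) -> pd.DataFrame:
    """Tabulate fits (one row per gene) with weights where defined."""
    rows = []
    for f in fits:
        row = {"gene_id": f.gene_id, "model_class": f.model_class,
               "dispersion": f.dispersion, "converged": f.converged,
               "diagnostic": f.diagnostic,
               "intercept": f.coefficients.get("intercept", np.nan)}
        for t in TERMS:
            row[f"beta_{t}"] = f.coefficients.get(t, np.nan)
            row[f"p_{t}"] = f.raw_p.get(t, np.nan)
            row[f"padj_{t}"] = f.adj_p.get(t, np.nan)
        if f.model_class in _WEIGHT_CLASSES:
            try:
                row["n_weight"], row["ndivw_weight"] = compute_nw_weights(f)
            except ValueError:
                row["n_weight"] = row["ndivw_weight"] = np.nan
        else:
            row["n_weight"] = row["ndivw_weight"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
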