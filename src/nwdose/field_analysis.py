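"""Field-side gene classification, lab-field conservation and phenotypes.

In the field the doses are categorical (fertilized or not, irrigated or
not), so each gene is modelled with an NB GLM on the 2x2 factorial plus a
genotype (cultivar) covariate, and term significance is judged by
analysis-of-deviance (likelihood-ratio) tests.  Genes with a significant
interaction are split by the sign of its log2 fold change: positive means
expression tracks matched high/high or low/low dose combinations (synergy,
N x W), negative means it tracks mismatched combinations, the behaviour of
concentration-responsive (N/W) genes.  The module also intersects lab and
field gene classes requiring a consistent regulation direction, selects the
dose model that best explains a phenotype, and evaluates the standard
moisture-corrected grain-yield formula.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import (
    TERMS,
    TERM_COLUMNS,
    AnalysisConfig,
    CountMatrix,
    PhenotypeTable,
    TreatmentDesign,
    filter_low_counts,
)
from .dose_model import _fit_nb_glm, estimate_dispersion, size_factors

__all__ = [
    "FieldGeneResult",
    "GrainYieldInput",
    "PhenotypeModelResult",
    "fit_field_model",
    "bin_field_genes",
    "conserved_direction",
    "grain_yield",
    "select_phenotype_model",
]

_FIELD_TERMS = ("N", "W", "N:W")


@dataclass
class FieldGeneResult:
    """Deviance-test results and classification for one field gene."""

    gene_id: str
    raw_p: dict[str, float] = field(default_factory=dict)  # keys N, W, N:W
    adj_p: dict[str, float] = field(default_factory=dict)
    log2_interaction_fc: float = np.nan
    field_class: str = "none"  # N, W, NdivW, NxW or none
    direction: str = "none"  # sign of the high-N/high-W contrast
    dispersion: float = np.nan
    converged: bool = True
    diagnostic: str = ""


def _field_design_matrix(design: TreatmentDesign) -> tuple[np.ndarray, dict[str, int], int]:
    """Full model matrix: intercept, N, W, N:W indicators + cultivar dummies.

    Returns the matrix, the column index of each dose term, and the number
    of dose columns (genotype dummies follow them).
    """
    n_ind = (design.frame["n_level"] > 0).to_numpy(dtype=float)
    w_ind = (design.frame["w_level"] > 0).to_numpy(dtype=float)
    cultivars = design.frame["cultivar"]
    dummies = pd.get_dummies(cultivars, drop_first=True, dtype=float)
    X = np.column_stack([np.ones(design.n_samples), n_ind, w_ind,
                         n_ind * w_ind, dummies.to_numpy()])
    return X, {"N": 1, "W": 2, "N:W": 3}, 4


def fit_field_model(
    counts: CountMatrix,
    design: TreatmentDesign,
    config: AnalysisConfig | None = None,
    prefiltered: bool = False,
    extra_offset: Mapping[str, float] | None = None,
) -> list[FieldGeneResult]:
    """Per-gene NB GLM on the 2x2 field factorial with a genotype covariate.

    Term p-values are likelihood-ratio (analysis-of-deviance) tests of the
    full model against the model with that term removed, at the per-gene
    dispersion of the full fit; BH adjustment is per term across genes.
    The genotype covariate absorbs cultivar differences and is never used
    to subset.  ``extra_offset`` adds known per-sample log-scale offsets
    (e.g. exposure adjustments) to the size-factor offset.
    """
    config = config or AnalysisConfig()
    if not design.is_field:
        raise ValueError("design lacks cultivar labels")
    counts.check_matches_design(design)
    if not prefiltered:
        counts = filter_low_counts(counts, config)
    factors = size_factors(counts)
    offset = np.log(factors.to_numpy())
    if extra_offset is not None:
        offset = offset + np.asarray(
            [float(extra_offset[s]) for s in design.sample_ids])

    X_full, term_col, n_dose = _field_design_matrix(design)
    values = counts.values()

    results: list[FieldGeneResult] = []
    for g, gene_id in enumerate(counts.gene_ids):
        res = FieldGeneResult(gene_id)
        y = values[g]
        try:
            pois = sm.GLM(y, X_full, family=sm.families.Poisson(),
                          offset=offset).fit()
            phi = estimate_dispersion(y, pois.mu, X_full)
            full = sm.GLM(y, X_full,
                          family=sm.families.NegativeBinomial(alpha=phi),
                          offset=offset).fit()
            if not np.all(np.isfinite(full.params)):
                raise ValueError("non-finite coefficients")
        except Exception as exc:  # noqa: BLE001 - flagged, never dropped
            res.converged = False
            res.diagnostic = f"full-model fit failed: {exc}"
            results.append(res)
            continue

        res.dispersion = phi
        res.log2_interaction_fc = float(full.params[term_col["N:W"]] / np.log(2))
        contrast = float(full.params[term_col["N"]] + full.params[term_col["W"]]
                         + full.params[term_col["N:W"]])
        res.direction = ("induced" if contrast > 0
                         else "repressed" if contrast < 0 else "none")
        for term, col in term_col.items():
            X_red = np.delete(X_full, col, axis=1)
            try:
                red = sm.GLM(y, X_red,
                             family=sm.families.NegativeBinomial(alpha=phi),
                             offset=offset).fit()
                lr = max(2.0 * (full.llf - red.llf), 0.0)
                res.raw_p[term] = float(stats.chi2.sf(lr, df=1))
            except Exception as exc:  # noqa: BLE001
                res.converged = False
                res.diagnostic = f"deviance test for {term} failed: {exc}"
        results.append(res)

    for term in _FIELD_TERMS:
        carriers = [r for r in results if r.converged and term in r.raw_p]
        if carriers:
            adj = multipletests([r.raw_p[term] for r in carriers],
                                method="fdr_bh")[1]
            for r, p in zip(carriers, adj):
                r.adj_p[term] = float(p)
    bin_field_genes(results, config)
    return results


def bin_field_genes(
    results: Sequence[FieldGeneResult],
    config: AnalysisConfig | None = None,
) -> dict[str, set[str]]:
    """Assign field classes in place and return the per-class gene sets.

    N (resp. W): that main term significant, the other main term and the
    interaction not.  A significant interaction overrides: NxW when its
    log2 fold change is positive, NdivW when negative; an exactly zero fold
    change with a significant interaction is flagged as a tie.
    """
    config = config or AnalysisConfig()
    alpha = config.assoc_alpha
    sets: dict[str, set[str]] = {"N": set(), "W": set(), "NdivW": set(),
                                 "NxW": set(), "none": set()}
    for r in results:
        if not r.converged or len(r.adj_p) < 3:
            r.field_class = "none"
            sets["none"].add(r.gene_id)
            continue
        sig = {t: r.adj_p[t] < alpha for t in _FIELD_TERMS}
        if sig["N:W"]:
            if r.log2_interaction_fc > 0:
                r.field_class = "NxW"
            elif r.log2_interaction_fc < 0:
                r.field_class = "NdivW"
            else:
                r.field_class = "none"
                r.diagnostic = "significant interaction with zero fold change"
        elif sig["N"] and not sig["W"]:
            r.field_class = "N"
        elif sig["W"] and not sig["N"]:
            r.field_class = "W"
        else:
            r.field_class = "none"
        sets[r.field_class].add(r.gene_id)
    return sets


def conserved_direction(
    lab_sets: Mapping[str, Mapping[str, str]],
    field_sets: Mapping[str, Mapping[str, str]],
) -> dict[str, dict[str, str]]:
    """Per-class genes regulated in the same direction in lab and field.

    Both inputs map class -> {gene_id -> "induced"/"repressed"}; the output
    keeps, per class, the genes present in both with matching direction.
    """
    out: dict[str, dict[str, str]] = {}
    for cls in lab_sets:
        lab = lab_sets[cls]
        fld = field_sets.get(cls, {})
        out[cls] = {g: d for g, d in lab.items() if fld.get(g) == d}
    return out


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrainYieldInput:
    """Inputs to the moisture-corrected grain-yield formula."""

    grain_weight: float  # g
    moisture_content: float  # percent
    sampling_area: float  # m2

    def __post_init__(self) -> None:
        if self.grain_weight < 0:
            raise ValueError("grain_weight must be non-negative")
        if not 0.0 <= self.moisture_content <= 100.0:
            raise ValueError("moisture_content must lie in [0, 100]")
        if self.sampling_area <= 0:
            raise ValueError("sampling_area must be positive")


def grain_yield(inp: GrainYieldInput) -> float:
    """Grain yield (g/m2), grain weight corrected to the 14% moisture
    standard: ``weight * ((100 - moisture) / 86) / area``."""
    return inp.grain_weight * ((100.0 - inp.moisture_content) / 86.0) \
        / inp.sampling_area


@dataclass
class PhenotypeModelResult:
    """Backward-elimination outcome for one phenotype."""

    selected: tuple[str, ...]  # surviving dose terms, () when none fit
    term_p: dict[str, float] = field(default_factory=dict)
    coefficients: dict[str, float] = field(default_factory=dict)
    anova_interaction_f: float = np.nan
    anova_interaction_p: float = np.nan
    note: str = ""


def select_phenotype_model(
    phenotype: pd.Series,
    design: TreatmentDesign,
    config: AnalysisConfig | None = None,
) -> PhenotypeModelResult:
    """Which dose terms best explain a phenotype.

    Fits a Gaussian linear model on log2 phenotype over the standardized
    dose predictors (plus cultivar dummies for field designs) and runs the
    same backward elimination as the gene models: drop the least significant
    term until all survivors pass ``model_alpha``.  For factorial designs
    the classical ANOVA F and p of the categorical N-by-W interaction are
    reported alongside.
    """
    config = config or AnalysisConfig()
    y = phenotype.reindex(design.sample_ids)
    if y.isna().any():
        missing = y.index[y.isna()].tolist()
        raise ValueError(f"phenotype missing for samples: {missing[:5]}")
    if (y <= 0).any():
        raise ValueError("phenotype must be positive for the log2 transform")
    logy = np.log2(y.to_numpy(dtype=float))
    if np.ptp(logy) == 0:
        return PhenotypeModelResult((), note="constant phenotype; no model")

    pred = design.predictors()
    covars = [np.ones(design.n_samples)]
    if design.is_field:
        covars.append(pd.get_dummies(design.frame["cultivar"], drop_first=True,
                                     dtype=float).to_numpy())
    base = np.column_stack(covars)

    terms = list(TERMS)
    result = PhenotypeModelResult(())
    while terms:
        X = np.column_stack(
            [base] + [pred[TERM_COLUMNS[t]].to_numpy() for t in terms])
        fit = sm.OLS(logy, X).fit()
        start = base.shape[1]
        pvals = {t: float(fit.pvalues[start + i]) for i, t in enumerate(terms)}
        if all(p < config.model_alpha for p in pvals.values()):
            result.selected = tuple(t for t in TERMS if t in terms)
            result.term_p = pvals
            result.coefficients = {t: float(fit.params[start + i])
                                   for i, t in enumerate(terms)}
            break
        worst = max(terms, key=lambda t: (pvals[t], TERMS.index(t)))
        terms.remove(worst)

    result.anova_interaction_f, result.anova_interaction_p = \
        _anova_interaction(logy, design)
    return result


def _anova_interaction(logy: np.ndarray, design: TreatmentDesign) -> tuple[float, float]:
    """F and p of the categorical N-by-W interaction (genotype-adjusted)."""
    frame = pd.DataFrame({
        "y": logy,
        "n": pd.Categorical(design.frame["n_level"]),
        "w": pd.Categorical(design.frame["w_level"]),
    })
    formula = "y ~ C(n) * C(w)"
    if design.is_field:
        frame["genotype"] = pd.Categorical(design.frame["cultivar"])
        formula += " + C(genotype)"
    fit = smf.ols(formula, data=frame).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    row = table.loc["C(n):C(w)"]
    return float(row["F"]), float(row["PR(>F)"])
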