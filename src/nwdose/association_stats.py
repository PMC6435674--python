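"""Gene-phenotype association, gene-set overlap and eigengene statistics.

Three inferential tools connect gene classes to phenotypes: a per-gene
Pearson/FDR correlation screen, a Monte-Carlo test for the overlap of two
gene sets against random draws from a declared background, and eigengene
analysis — the first principal component of a gene set's log2 expression,
whose association with a phenotype is judged against a null of eigengenes
built from random same-size gene sets.  Eigengene correlations are reported
as magnitudes because a principal component's sign is arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import AnalysisConfig, CountMatrix
from .dose_model import size_factors

__all__ = [
    "Eigengene",
    "OverlapResult",
    "EigengeneAssociation",
    "pearson_fdr",
    "monte_carlo_overlap",
    "adjust_overlaps",
    "build_eigengene",
    "eigengene_assoc",
    "normalize_unit_interval",
]


# ---------------------------------------------------------------------------
# Pearson/FDR screen
# ---------------------------------------------------------------------------


def pearson_fdr(
    expr: pd.DataFrame,
    phenotype: pd.Series,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Per-gene Pearson correlation with a phenotype, BH-adjusted.

    ``expr`` holds normalized per-gene values (genes x samples);
    ``phenotype`` is indexed by sample id (log2-transform upstream where
    appropriate).  Constant genes (or a constant phenotype) have no defined
    correlation and are flagged non-significant with a reason.
    """
    config = config or AnalysisConfig()
    pheno = phenotype.reindex(expr.columns)
    if pheno.isna().any():
        missing = pheno.index[pheno.isna()].tolist()
        raise ValueError(f"phenotype missing for samples: {missing[:5]}")
    X = expr.to_numpy(dtype=float)
    y = pheno.to_numpy(dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 samples")

    yc = y - y.mean()
    sy = np.sqrt((yc ** 2).sum())
    Xc = X - X.mean(axis=1, keepdims=True)
    sx = np.sqrt((Xc ** 2).sum(axis=1))
    degenerate = (sx == 0) | (sy == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ yc) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = np.where(np.isinf(t), 0.0, 2.0 * stats.t.sf(np.abs(t), n - 2))
    r[degenerate] = np.nan
    p[degenerate] = np.nan

    adj = np.full(len(r), np.nan)
    valid = ~degenerate
    if valid.any():
        adj[valid] = multipletests(p[valid], method="fdr_bh")[1]
    out = pd.DataFrame({
        "r": r, "raw_p": p, "adj_p": adj,
        "significant": valid & (adj < config.assoc_alpha),
        "reason": np.where(degenerate,
                           "constant phenotype" if sy == 0 else "constant gene",
                           ""),
    }, index=expr.index.rename("gene_id"))
    return out


# ---------------------------------------------------------------------------
# Monte-Carlo gene-set overlap
# ---------------------------------------------------------------------------


@dataclass
class OverlapResult:
    """Monte-Carlo overlap test between two gene sets."""

    n_a: int
    n_b: int
    n_background: int
    observed: int
    p: float
    n_perm: int
    adj_p: float = np.nan


def monte_carlo_overlap(
    set_a: Sequence[str],
    set_b: Sequence[str],
    background: Sequence[str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> OverlapResult:
    """Is the overlap of two gene sets larger than chance?

    Null draws pick ``|set_a|`` genes uniformly without replacement from the
    background and count the overlap with ``set_b``; the add-one estimate
    ``p = (1 + #{perm overlap >= observed}) / (1 + n_perm)`` is never
    exactly zero and is reproducible for a fixed seed.
    """
    set_a, set_b = set(set_a), set(set_b)
    bg = list(dict.fromkeys(background))
    bg_set = set(bg)
    offenders = sorted((set_a | set_b) - bg_set)
    if offenders:
        raise ValueError(f"genes outside background: {offenders[:10]}")
    observed = len(set_a & set_b)

    rng = np.random.default_rng(seed)
    in_b = np.asarray([g in set_b for g in bg])
    n_a = len(set_a)
    hits = 0
    for _ in range(n_perm):
        idx = rng.choice(len(bg), size=n_a, replace=False)
        if in_b[idx].sum() >= observed:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return OverlapResult(n_a, len(set_b), len(bg), observed, p, n_perm)


def adjust_overlaps(results: Sequence[OverlapResult]) -> None:
    """BH-adjust Monte-Carlo p-values across a family of tested pairs."""
    if not results:
        return
    adj = multipletests([r.p for r in results], method="fdr_bh")[1]
    for r, a in zip(results, adj):
        r.adj_p = float(a)


# ---------------------------------------------------------------------------
# Eigengenes
# ---------------------------------------------------------------------------


@dataclass
class Eigengene:
    """First principal component of a gene set's log2 expression."""

    gene_set_id: str
    scores: pd.Series  # one value per sample; sign arbitrary
    variance_proportion: float
    n_genes: int
    associations: dict[str, "EigengeneAssociation"] = field(default_factory=dict)


@dataclass
class EigengeneAssociation:
    """Permutation-tested eigengene-phenotype association."""

    abs_r: float
    p: float
    significant: bool
    n_perm: int
    reason: str = ""


def _log2_normalized(counts: CountMatrix, factors: pd.Series) -> np.ndarray:
    aligned = factors.reindex(counts.sample_ids)
    if aligned.isna().any():
        raise ValueError("size factors missing for some samples")
    return np.log2(counts.values() / aligned.to_numpy() + 1.0)


def _pc1_scores(log_expr: np.ndarray) -> tuple[np.ndarray, float]:
    """PC1 sample scores and variance proportion of a genes x samples block."""
    centered = log_expr - log_expr.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    total = float((s ** 2).sum())
    if total == 0:
        return np.zeros(log_expr.shape[1]), 1.0
    return s[0] * vt[0], float(s[0] ** 2 / total)


def build_eigengene(
    expr: CountMatrix,
    factors: pd.Series | None = None,
    gene_set_id: str = "",
) -> Eigengene:
    """Eigengene of a gene set: PC1 of its log2 normalized expression.

    Counts are normalized by size factors (computed from ``expr`` itself
    when not supplied), log2-transformed with a pseudocount of 1, and
    centered per gene; the per-sample PC1 scores summarize the set's
    expression trend in one profile.
    """
    n_genes, n_samples = expr.shape
    if n_genes < 1:
        raise ValueError("gene set is empty")
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    if factors is None:
        factors = size_factors(expr)
    scores, varprop = _pc1_scores(_log2_normalized(expr, factors))
    return Eigengene(gene_set_id, pd.Series(scores, index=expr.sample_ids),
                     varprop, n_genes)


def eigengene_assoc(
    eigengene: Eigengene,
    phenotype: pd.Series,
    background_expr: CountMatrix,
    n_perm: int = 10_000,
    seed: int = 0,
    factors: pd.Series | None = None,
    alpha: float = 0.05,
) -> EigengeneAssociation:
    """Permutation test of an eigengene-phenotype association.

    The statistic is |Pearson r| between the eigengene scores and the
    phenotype (log2-transform the phenotype upstream where appropriate).
    The null rebuilds an eigengene from a random gene set of the same size,
    drawn without replacement from the background expression matrix, for
    each of ``n_perm`` permutations; the add-one p-value counts null |r|
    values at least as large as the observed one.
    """
    pheno = phenotype.reindex(eigengene.scores.index)
    if pheno.isna().any():
        raise ValueError("phenotype missing for some eigengene samples")
    y = pheno.to_numpy(dtype=float)
    if np.ptp(y) == 0:
        return EigengeneAssociation(np.nan, np.nan, False, n_perm,
                                    reason="constant phenotype")
    if list(background_expr.sample_ids) != list(eigengene.scores.index):
        raise ValueError("background samples do not match eigengene samples")
    if eigengene.n_genes > background_expr.shape[0]:
        raise ValueError("gene set larger than background")

    observed = _abs_pearson(eigengene.scores.to_numpy(), y)
    if factors is None:
        factors = size_factors(background_expr)
    log_bg = _log2_normalized(background_expr, factors)

    rng = np.random.default_rng(seed)
    n_bg = log_bg.shape[0]
    hits = 0
    for _ in range(n_perm):
        idx = rng.choice(n_bg, size=eigengene.n_genes, replace=False)
        scores, _ = _pc1_scores(log_bg[idx])
        if _abs_pearson(scores, y) >= observed:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return EigengeneAssociation(observed, p, p < alpha, n_perm)


def _abs_pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a ** 2).sum() * (b ** 2).sum())
    if denom == 0:
        return 0.0
    return float(abs((a * b).sum() / denom))


# ---------------------------------------------------------------------------
# Heatmap normalization
# ---------------------------------------------------------------------------


def normalize_unit_interval(expr: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Scale each gene's values to [0, 1], the maximum mapping to 1.

    Returns the rescaled frame and a boolean flag per gene marking constant
    genes, which are set to all zeros by convention.
    """
    X = expr.to_numpy(dtype=float)
    lo = X.min(axis=1, keepdims=True)
    hi = X.max(axis=1, keepdims=True)
    span = hi - lo
    constant = span[:, 0] == 0
    span[constant] = 1.0
    out = (X - lo) / span
    out[constant] = 0.0
    return (pd.DataFrame(out, index=expr.index, columns=expr.columns),
            pd.Series(constant, index=expr.index, name="constant"))
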