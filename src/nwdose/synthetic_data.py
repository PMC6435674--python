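"""Synthetic factorial RNA-seq data with known ground truth.

Generates negative-binomial count matrices whose log-means are linear in
the standardized dose predictors (N, W, N/W, N×W), phenotypes with a
configurable dose dependence, field data with per-cultivar baseline
offsets, and paired treated/control time courses with a saturating
nitrogen-uptake curve.  Every gene carries a truth record so downstream
classifiers can be scored against a recoverable answer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    TERMS,
    TERM_COLUMNS,
    CountMatrix,
    PhenotypeTable,
    TreatmentDesign,
)

__all__ = [
    "SyntheticTruth",
    "TimecourseSim",
    "simulate_lab_counts",
    "simulate_phenotypes",
    "simulate_timecourse",
    "simulate_field_counts",
]

#: Default log-mean range for simulated baselines (natural log of roughly
#: 50-500 reads, a moderately expressed gene).
_BASELINE_LOG_RANGE = (np.log(50.0), np.log(500.0))


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one simulated gene."""

    gene_id: str
    true_class: str  # "N", "W", "NdivW", "NxW", "N+NdivW", ..., or "null"
    betas: Mapping[str, float]  # effect per term on standardized predictors
    baseline_log_mean: float
    dispersion: float
    direction: str  # "induced" or "repressed" ("none" for null genes)

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        active = {t for t, b in self.betas.items() if b != 0.0}
        expected = set() if self.true_class == "null" else set(self.true_class.split("+"))
        if active != expected:
            raise ValueError(
                f"{self.gene_id}: class {self.true_class!r} inconsistent with "
                f"nonzero betas {sorted(active)}")


def truth_frame(truths: Sequence[SyntheticTruth]) -> pd.DataFrame:
    """Tabulate truth records (one row per gene) for TSV output."""
    rows = []
    for t in truths:
        row = {"gene_id": t.gene_id, "true_class": t.true_class,
               "baseline_log_mean": t.baseline_log_mean,
               "dispersion": t.dispersion, "direction": t.direction}
        for term in TERMS:
            row[f"beta_{term}"] = t.betas.get(term, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def _class_assignments(n_genes: int,
                       class_proportions: Mapping[str, float],
                       rng: np.random.Generator) -> list[str]:
    classes = list(class_proportions)
    probs = np.asarray([class_proportions[c] for c in classes], dtype=float)
    if (probs < 0).any():
        raise ValueError("class proportions must be non-negative")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"class proportions must sum to 1, got {probs.sum()}")
    for cls in classes:
        if cls != "null":
            unknown = set(cls.split("+")) - set(TERMS)
            if unknown:
                raise ValueError(f"unknown terms in class {cls!r}: {sorted(unknown)}")
    # deterministic block assignment (exact proportions up to rounding),
    # then shuffled so gene order carries no information
    counts = np.floor(probs * n_genes).astype(int)
    counts[np.argmax(probs)] += n_genes - counts.sum()
    labels = np.repeat(classes, counts)
    rng.shuffle(labels)
    return labels.tolist()


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """Negative-binomial counts with variance mu + dispersion * mu^2."""
    size = 1.0 / dispersion
    return rng.negative_binomial(size, size / (size + mean))


def _draw_gene(rng: np.random.Generator, gene_id: str, cls: str,
               effect_size: float, dispersion: float) -> SyntheticTruth:
    baseline = rng.uniform(*_BASELINE_LOG_RANGE)
    if cls == "null" or effect_size == 0.0:
        return SyntheticTruth(gene_id, "null", {t: 0.0 for t in TERMS},
                              baseline, dispersion, "none")
    sign = 1.0 if rng.random() < 0.5 else -1.0
    betas = {t: (sign * effect_size if t in cls.split("+") else 0.0)
             for t in TERMS}
    return SyntheticTruth(gene_id, cls, betas, baseline, dispersion,
                          "induced" if sign > 0 else "repressed")


def simulate_lab_counts(
    design: TreatmentDesign,
    n_genes: int,
    class_proportions: Mapping[str, float],
    effect_size: float = 1.0,
    dispersion: float = 0.05,
    seed: int = 0,
    size_factor_sd: float = 0.0,
) -> tuple[CountMatrix, list[SyntheticTruth]]:
    """Factorial counts whose log-mean is linear in the dose predictors.

    Per gene: ``log mu = baseline + sum(beta_t * predictor_t)`` on the
    standardized predictors, counts negative-binomial with the given
    dispersion.  ``size_factor_sd > 0`` adds per-sample lognormal depth
    multipliers.
    """
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    if effect_size < 0:
        raise ValueError("effect_size must be non-negative")
    rng = np.random.default_rng(seed)
    classes = _class_assignments(n_genes, class_proportions, rng)
    predictors = design.predictors().to_numpy()  # samples x 4

    depth = np.exp(rng.normal(0.0, size_factor_sd, design.n_samples)) \
        if size_factor_sd > 0 else np.ones(design.n_samples)

    truths, rows = [], np.empty((n_genes, design.n_samples), dtype=np.int64)
    for g in range(n_genes):
        truth = _draw_gene(rng, f"gene{g:05d}", classes[g], effect_size, dispersion)
        beta = np.asarray([truth.betas[t] for t in TERMS])
        mu = np.exp(truth.baseline_log_mean + predictors @ beta) * depth
        rows[g] = _nb_draw(rng, mu, dispersion)
        truths.append(truth)

    counts = CountMatrix(pd.DataFrame(
        rows, index=[t.gene_id for t in truths], columns=design.sample_ids))
    return counts, truths


def simulate_phenotypes(
    design: TreatmentDesign,
    coef: Mapping[str, float],
    noise_sd: float = 0.1,
    seed: int = 0,
) -> PhenotypeTable:
    """Phenotypes with a configurable dose dependence.

    ``log2(shoot_biomass) = coef[intercept] + sum(coef[t] * predictor_t)
    + Gaussian noise``.  Leaf N-content rises with the N dose and delta-13C
    falls with the W dose (wetter plants discriminate more), so both
    auxiliary traits are monotone in their driving predictor.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    unknown = set(coef) - ({"intercept"} | set(TERMS))
    if unknown:
        raise ValueError(f"unknown coefficient keys: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    pred = design.predictors()
    eta = np.full(design.n_samples, float(coef.get("intercept", 0.0)))
    for term in TERMS:
        eta = eta + float(coef.get(term, 0.0)) * pred[TERM_COLUMNS[term]].to_numpy()
    log2_biomass = eta + rng.normal(0.0, noise_sd, design.n_samples)

    n_std = design.frame["n_std"].to_numpy()
    w_std = design.frame["w_std"].to_numpy()
    data = pd.DataFrame({
        "shoot_biomass": np.exp2(log2_biomass),
        # leaf N fraction: rises with supplied N, mild noise
        "n_content": 2.0 + 0.5 * n_std + rng.normal(0.0, noise_sd / 4, design.n_samples),
        # delta-13C (permil): less negative when water is scarce
        "wue_delta13c": -29.0 - 1.0 * w_std + rng.normal(0.0, noise_sd, design.n_samples),
    }, index=pd.Index(design.sample_ids, name="sample_id"))
    return PhenotypeTable(data)


class TimecourseSim(NamedTuple):
    """Paired treated/control time-course matrices plus metadata."""

    treated: CountMatrix
    control: CountMatrix
    times: np.ndarray  # time (min) of each column, shared by both arms
    uptake_curve: np.ndarray  # cumulative tracer uptake per unique timepoint
    truths: list[SyntheticTruth]
    onsets: dict[str, float]  # responder gene -> onset time (min)


DEFAULT_TIMEPOINTS = (0, 5, 10, 15, 20, 30, 45, 60, 90, 120)


def simulate_timecourse(
    times: Sequence[float] = DEFAULT_TIMEPOINTS,
    n_genes: int = 500,
    n_responders: int = 100,
    replicates: int = 3,
    onset_minutes: Mapping[str, float] | float | None = None,
    fold: float = 4.0,
    dispersion: float = 0.05,
    seed: int = 0,
    uptake_tau: float = 30.0,
) -> TimecourseSim:
    """Paired N-treated / mock-treated count series over a 0-120 min course.

    Responder genes shift their log-mean by ``log(fold)`` in the treated arm
    only, from their onset time onward (induced or repressed with equal
    probability); the control arm is stationary.  Tracer uptake follows a
    saturating ``1 - exp(-t / tau)`` curve, zero at t = 0.
    """
    times = np.asarray(sorted(float(t) for t in times))
    if 0.0 not in times:
        raise ValueError("times must include 0")
    if not 0 <= n_responders <= n_genes:
        raise ValueError("need 0 <= n_responders <= n_genes")
    if fold <= 0:
        raise ValueError("fold must be positive")
    rng = np.random.default_rng(seed)

    gene_ids = [f"gene{g:05d}" for g in range(n_genes)]
    responder_ids = list(rng.choice(gene_ids, size=n_responders, replace=False))

    onsets: dict[str, float] = {}
    positive_times = times[times > 0]
    for gid in responder_ids:
        if onset_minutes is None:
            onsets[gid] = float(rng.choice(positive_times))
        elif isinstance(onset_minutes, Mapping):
            onsets[gid] = float(onset_minutes[gid])
        else:
            onsets[gid] = float(onset_minutes)
    bad = {g: t for g, t in onsets.items() if not times[0] < t <= times[-1]}
    if bad:
        raise ValueError(f"onset outside time range: {bad}")

    col_times = np.repeat(times, replicates)
    columns = [f"t{int(t):03d}_r{r + 1}"
               for t in times for r in range(replicates)]

    truths, treated_rows, control_rows = [], [], []
    for gid in gene_ids:
        baseline = rng.uniform(*_BASELINE_LOG_RANGE)
        if gid in onsets:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            direction = "induced" if sign > 0 else "repressed"
            shift = np.where(col_times >= onsets[gid], sign * np.log(fold), 0.0)
        else:
            direction, shift = "none", np.zeros_like(col_times)
        mu_control = np.full_like(col_times, np.exp(baseline))
        mu_treated = np.exp(baseline + shift)
        treated_rows.append(_nb_draw(rng, mu_treated, dispersion))
        control_rows.append(_nb_draw(rng, mu_control, dispersion))
        truths.append(SyntheticTruth(
            gid, "null", {t: 0.0 for t in TERMS}, baseline, dispersion, direction))

    uptake = 1.0 - np.exp(-times / uptake_tau)
    treated = CountMatrix(pd.DataFrame(np.asarray(treated_rows), index=gene_ids,
                                       columns=columns))
    control = CountMatrix(pd.DataFrame(np.asarray(control_rows), index=gene_ids,
                                       columns=columns))
    return TimecourseSim(treated, control, col_times, uptake, truths, onsets)


def simulate_field_counts(
    design: TreatmentDesign,
    n_genes: int,
    class_proportions: Mapping[str, float],
    genotype_sd: float = 0.3,
    effect_size: float = 1.0,
    dispersion: float = 0.05,
    seed: int = 0,
) -> tuple[CountMatrix, list[SyntheticTruth]]:
    """2x2 factorial field counts with per-cultivar baseline offsets.

    Effects act on the 0/1 N and W indicators: N genes respond to the
    fertilizer main effect, W genes to irrigation, synergy (NxW) genes get a
    positive interaction on the log scale and concentration (NdivW) genes a
    negative one.  Each cultivar adds a Gaussian log-scale offset of
    standard deviation ``genotype_sd`` to every gene's baseline.
    """
    if not design.is_field:
        raise ValueError("design lacks cultivar labels; build_field_design required")
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    rng = np.random.default_rng(seed)
    classes = _class_assignments(n_genes, class_proportions, rng)

    n_ind = (design.frame["n_level"] > 0).to_numpy(dtype=float)
    w_ind = (design.frame["w_level"] > 0).to_numpy(dtype=float)
    cultivars = design.frame["cultivar"].to_numpy()
    unique_cultivars = list(dict.fromkeys(cultivars))

    truths, rows = [], np.empty((n_genes, design.n_samples), dtype=np.int64)
    for g in range(n_genes):
        gid = f"gene{g:05d}"
        cls = classes[g]
        baseline = rng.uniform(*_BASELINE_LOG_RANGE)
        offsets = dict(zip(unique_cultivars,
                           rng.normal(0.0, genotype_sd, len(unique_cultivars))
                           if genotype_sd > 0 else np.zeros(len(unique_cultivars))))
        eta = baseline + np.asarray([offsets[c] for c in cultivars])
        betas = {t: 0.0 for t in TERMS}
        direction = "none"
        if cls != "null" and effect_size > 0:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            terms = cls.split("+")
            if "N" in terms:
                betas["N"] = sign * effect_size
                eta = eta + betas["N"] * n_ind
            if "W" in terms:
                betas["W"] = sign * effect_size
                eta = eta + betas["W"] * w_ind
            if "NxW" in terms:  # synergy: positive interaction
                betas["NxW"] = effect_size
                eta = eta + effect_size * n_ind * w_ind
            if "NdivW" in terms:  # concentration: negative interaction
                betas["NdivW"] = -effect_size
                eta = eta - effect_size * n_ind * w_ind
            # direction = sign of the high-N/high-W contrast, matching the
            # convention the field classifier reports
            contrast = betas["N"] + betas["W"] + betas["NxW"] + betas["NdivW"]
            if contrast > 0:
                direction = "induced"
            elif contrast < 0:
                direction = "repressed"
            else:
                direction = "induced" if sign > 0 else "repressed"
        cls_out = cls if direction != "none" else "null"
        rows[g] = _nb_draw(rng, np.exp(eta), dispersion)
        truths.append(SyntheticTruth(gid, cls_out, betas, baseline,
                                     dispersion, direction))

    counts = CountMatrix(pd.DataFrame(
        rows, index=[t.gene_id for t in truths], columns=design.sample_ids))
    return counts, truths
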