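"""Domain types, experimental designs, file I/O and shared gene filtering.

The package analyses factorial nitrogen-by-water (N-by-W) dose experiments:
a lab design crossing four ammonium-nitrate concentrations with four water
volumes (triplicate, 48 samples), and a field design crossing two
N-fertilizer doses with two irrigation regimes over a panel of rice
cultivars.  Every downstream model works on four dose predictors derived
from the design: N-moles (absolute nitrogen supplied), W-volume (water
present), N-molarity N/W (concentration), and the synergy product N×W.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TERMS",
    "TERM_COLUMNS",
    "InvalidDesignError",
    "ParseError",
    "AnalysisConfig",
    "TreatmentDesign",
    "CountMatrix",
    "PhenotypeTable",
    "build_lab_design",
    "build_field_design",
    "filter_low_counts",
    "read_counts",
    "write_counts",
    "read_design",
    "write_design",
    "read_phenotypes",
    "write_phenotypes",
]

#: Dose terms in the fixed model order used everywhere (elimination
#: tie-breaks, subset enumeration, output columns).
TERMS: tuple[str, ...] = ("N", "W", "NdivW", "NxW")

#: Standardized design-matrix column backing each dose term.
TERM_COLUMNS: Mapping[str, str] = {
    "N": "n_std",
    "W": "w_std",
    "NdivW": "ndivw_std",
    "NxW": "nxw_std",
}

#: Volume (L) of feed solution at full saturation; converts a supplied
#: concentration (mM) into an absolute N amount (mmol).
FEED_VOLUME_L = 0.130

#: Field N-fertilizer doses (kg/ha): unfertilized vs high-dose.
FIELD_N_LEVELS = (0.0, 150.0)


class InvalidDesignError(ValueError):
    """Raised when an experimental design cannot be constructed."""


class ParseError(ValueError):
    """Raised when a TSV file cannot be parsed into a domain type."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and sizes shared by the analysis stages.

    Parameters
    ----------
    model_alpha:
        FDR threshold for dose-model terms during backward elimination.
    assoc_alpha:
        FDR threshold for correlation screens and field differential
        expression.
    min_total_count:
        Genes with a total read count (summed over samples) below this are
        discarded before modelling.
    min_median_count:
        Genes whose median count falls below this are discarded.
    spline_df:
        Total degrees of freedom (including intercept) of the per-arm cubic
        spline in the time-course model.
    spline_knots:
        Number of interior knots of that spline.
    fc_threshold:
        Fold-change magnitude a differentially expressed gene must exceed
        (strictly) at a timepoint to be binned there.
    timecourse_min_total:
        Minimum combined read count across all timepoints (both arms) for a
        gene to be eligible for a differential-expression call.
    n_perm:
        Number of Monte-Carlo permutations for overlap and eigengene nulls.
    seed:
        Default seed for stochastic procedures.
    """

    model_alpha: float = 0.005
    assoc_alpha: float = 0.05
    min_total_count: int = 128
    min_median_count: int = 1
    spline_df: int = 5
    spline_knots: int = 3
    fc_threshold: float = 1.25
    timecourse_min_total: int = 100
    n_perm: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("model_alpha", "assoc_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1); got {v!r}")
        for name in ("min_total_count", "min_median_count", "spline_df",
                     "spline_knots", "timecourse_min_total", "n_perm"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer; got {v!r}")
        if self.fc_threshold <= 1.0:
            raise ValueError("fc_threshold must exceed 1")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(mapping))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        if not isinstance(data, dict):
            raise ParseError(f"{path}: expected a mapping of config keys")
        return cls.from_mapping(data)

    def updated(self, **kwargs: object) -> "AnalysisConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Treatment designs
# ---------------------------------------------------------------------------


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()  # population SD so variance is exactly 1
    if sd == 0:
        raise InvalidDesignError("cannot standardize a constant predictor")
    return (x - x.mean()) / sd


def _with_standardized(frame: pd.DataFrame) -> pd.DataFrame:
    """Append z-scored predictor columns (mean 0, variance 1).

    The interaction column is the elementwise product of the standardized
    main effects, itself re-standardized, so it is not collinear with the
    main effects on a dose grid.
    """
    out = frame.copy()
    n_std = _zscore(out["n_level"].to_numpy())
    w_std = _zscore(out["w_level"].to_numpy())
    out["n_std"] = n_std
    out["w_std"] = w_std
    out["ndivw_std"] = _zscore(out["n_over_w"].to_numpy())
    out["n_times_w"] = n_std * w_std
    out["nxw_std"] = _zscore(out["n_times_w"].to_numpy())
    return out


@dataclass(frozen=True)
class TreatmentDesign:
    """Per-sample dose predictors plus replicate / cultivar labels.

    ``frame`` holds one row per sample with raw dose columns (``n_level``,
    ``w_level``, ``n_over_w``, ``n_times_w``), z-scored predictor columns
    (``n_std``, ``w_std``, ``ndivw_std``, ``nxw_std``), a ``replicate``
    integer and, for field designs, a ``cultivar`` label.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "n_level", "w_level", "n_over_w",
                    "n_times_w", "replicate",
                    "n_std", "w_std", "ndivw_std", "nxw_std"}
        missing = required - set(self.frame.columns)
        if missing:
            raise InvalidDesignError(f"design missing columns: {sorted(missing)}")
        if self.frame["sample_id"].duplicated().any():
            dupes = self.frame.loc[self.frame["sample_id"].duplicated(), "sample_id"]
            raise InvalidDesignError(f"duplicate sample ids: {sorted(set(dupes))}")
        if (self.frame["replicate"] < 1).any():
            raise InvalidDesignError("replicate labels must be >= 1")

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    @property
    def is_field(self) -> bool:
        return "cultivar" in self.frame.columns

    @property
    def n_samples(self) -> int:
        return len(self.frame)

    def predictors(self) -> pd.DataFrame:
        """Standardized predictor matrix (samples x 4), indexed by sample id."""
        cols = [TERM_COLUMNS[t] for t in TERMS]
        return self.frame.set_index("sample_id")[cols]

    def restandardized(self) -> "TreatmentDesign":
        """Recompute the standardized columns from the raw dose columns."""
        return TreatmentDesign(_with_standardized(
            self.frame.drop(columns=["n_std", "w_std", "ndivw_std",
                                     "nxw_std", "n_times_w"])))


def _check_levels(values: Sequence[float], what: str, expect: int | None) -> list[float]:
    vals = [float(v) for v in values]
    if expect is not None and len(vals) != expect:
        raise InvalidDesignError(f"expected {expect} {what} levels, got {len(vals)}")
    if any(v <= 0 for v in vals):
        raise InvalidDesignError(f"{what} levels must be positive: {vals}")
    if len(set(vals)) != len(vals):
        raise InvalidDesignError(f"{what} levels must be distinct: {vals}")
    return vals


def build_lab_design(
    n_conc_mM: Sequence[float] = (0.625, 1.25, 2.5, 5.0),
    w_volumes_mL: Sequence[float] = (16.25, 32.5, 65.0, 130.0),
    replicates: int = 3,
) -> TreatmentDesign:
    """Full-factorial lab design crossing 4 N concentrations with 4 W volumes.

    The N predictor is the absolute amount supplied (mmol): concentration
    (mM) times the fixed 130 mL feed volume.  ``n_over_w`` is the resulting
    concentration once the water volume has evaporated down to ``w_level``
    (mmol/mL = M; numerically mM per mL-scaled volume).
    """
    n_levels = _check_levels(n_conc_mM, "N concentration", 4)
    w_levels = _check_levels(w_volumes_mL, "W volume", 4)
    if replicates < 1:
        raise InvalidDesignError("replicates must be >= 1")

    rows = []
    for (conc, vol), rep in itertools.product(
            itertools.product(n_levels, w_levels), range(1, replicates + 1)):
        n_mmol = conc * FEED_VOLUME_L
        rows.append({
            "sample_id": f"N{conc:g}_W{vol:g}_r{rep}",
            "n_level": n_mmol,
            "w_level": vol,
            "n_over_w": n_mmol / vol,
            "replicate": rep,
        })
    return TreatmentDesign(_with_standardized(pd.DataFrame(rows)))


def build_field_design(
    cultivars: Sequence[str],
    replicates: int = 3,
) -> TreatmentDesign:
    """2-by-2 field design (N dose 0 vs 150 kg/ha; W deplete vs replete)
    replicated over a panel of cultivars."""
    cultivars = [str(c) for c in cultivars]
    if not cultivars:
        raise InvalidDesignError("at least one cultivar is required")
    if len(set(cultivars)) != len(cultivars):
        raise InvalidDesignError("cultivar names must be unique")
    if replicates < 1:
        raise InvalidDesignError("replicates must be >= 1")

    rows = []
    for cultivar in cultivars:
        for n_level in FIELD_N_LEVELS:
            for w_level in (0.0, 1.0):  # 0 = deplete, 1 = replete
                for rep in range(1, replicates + 1):
                    rows.append({
                        "sample_id": f"{cultivar}_N{n_level:g}_W{w_level:g}_r{rep}",
                        "n_level": n_level,
                        "w_level": w_level,
                        # bookkeeping concentration proxy: dose per unit
                        # water, with deplete coded as the smaller volume
                        "n_over_w": n_level / (1.0 + w_level),
                        "replicate": rep,
                        "cultivar": cultivar,
                    })
    return TreatmentDesign(_with_standardized(pd.DataFrame(rows)))


# ---------------------------------------------------------------------------
# Count matrices and phenotypes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CountMatrix:
    """Integer read counts, genes as rows and samples as columns."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()]
            raise ValueError(f"duplicate gene ids: {sorted(set(dupes))}")
        values = self.counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            raise ValueError("counts must be integers")
        if values.size and (values < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def values(self) -> np.ndarray:
        return self.counts.to_numpy()

    def subset_genes(self, gene_ids: Iterable[str]) -> "CountMatrix":
        gene_ids = list(gene_ids)
        missing = set(gene_ids) - set(self.counts.index)
        if missing:
            raise KeyError(f"genes absent from matrix: {sorted(missing)[:5]}")
        return CountMatrix(self.counts.loc[gene_ids])

    def check_matches_design(self, design: TreatmentDesign) -> None:
        if self.sample_ids != design.sample_ids:
            extra = set(self.sample_ids) ^ set(design.sample_ids)
            raise ValueError(
                "count columns do not match design rows"
                + (f"; mismatched ids: {sorted(extra)[:5]}" if extra else
                   " (same ids, different order)"))


@dataclass(frozen=True)
class PhenotypeTable:
    """Per-sample phenotype measurements, indexed by sample id.

    Core lab traits: ``shoot_biomass`` (g dry weight), ``n_content`` (leaf N
    fraction) and ``wue_delta13c`` (carbon-13 discrimination, a water-use
    efficiency proxy).  Field tables may add yield components such as
    ``grain_yield`` (g/m2), ``straw_biomass``, ``plant_height``,
    ``tiller_number``, ``panicle_number``, ``chlorophyll_index`` and
    ``stomatal_conductance``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValueError("duplicate sample ids in phenotype table")
        for col in ("shoot_biomass", "grain_yield", "straw_biomass"):
            if col in self.data.columns:
                vals = self.data[col].dropna()
                if (vals <= 0).any() and col == "shoot_biomass":
                    raise ValueError("shoot_biomass must be positive")

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    def check_matches_design(self, design: TreatmentDesign) -> None:
        extra = set(self.sample_ids) - set(design.sample_ids)
        if extra:
            raise ValueError(f"phenotype samples absent from design: {sorted(extra)[:5]}")

    def trait(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise KeyError(f"unknown trait {name!r}")
        return self.data[name]


def filter_low_counts(counts: CountMatrix, config: AnalysisConfig) -> CountMatrix:
    """Drop genes with too few reads to model.

    Retains genes whose total count across all samples is at least
    ``min_total_count`` and whose median count is at least
    ``min_median_count``; input order is preserved.
    """
    values = counts.values()
    keep = (values.sum(axis=1) >= config.min_total_count) & \
           (np.median(values, axis=1) >= config.min_median_count)
    if not keep.any():
        import warnings

        warnings.warn("no genes survive the count filter", stacklevel=2)
    return CountMatrix(counts.counts.loc[keep])


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if frame.columns.size == 0:
        raise ParseError(f"{path}: empty file")
    return frame


def read_counts(path: str | Path) -> CountMatrix:
    """Read a gene x sample count matrix from TSV (first column ``gene_id``)."""
    frame = _read_tsv(path)
    if frame.columns[0] != "gene_id":
        raise ParseError(f"{path}: first column must be 'gene_id', got "
                         f"{frame.columns[0]!r}")
    frame = frame.set_index("gene_id")
    columns = {}
    for col in frame.columns:
        try:
            columns[col] = frame[col].astype(np.int64)
        except (ValueError, TypeError):
            bad = frame[col][~frame[col].str.fullmatch(r"-?\d+")]
            line = frame.index.get_loc(bad.index[0]) + 2  # +1 header, +1 1-based
            raise ParseError(
                f"{path}: non-integer count {bad.iloc[0]!r} for gene "
                f"{bad.index[0]!r} (line {line}, column {col!r})") from None
    return CountMatrix(pd.DataFrame(columns, index=frame.index))


def write_counts(counts: CountMatrix, path: str | Path) -> None:
    counts.counts.rename_axis("gene_id").to_csv(path, sep="\t")


def read_design(path: str | Path) -> TreatmentDesign:
    frame = _read_tsv(path)
    numeric = ["n_level", "w_level", "n_over_w", "n_times_w",
               "n_std", "w_std", "ndivw_std", "nxw_std"]
    for col in numeric:
        if col in frame.columns:
            try:
                frame[col] = frame[col].astype(float)
            except ValueError as exc:
                raise ParseError(f"{path}: column {col!r}: {exc}") from None
    if "replicate" in frame.columns:
        try:
            frame["replicate"] = frame["replicate"].astype(np.int64)
        except ValueError:
            raise ParseError(f"{path}: non-integer replicate label") from None
    return TreatmentDesign(frame)


def write_design(design: TreatmentDesign, path: str | Path) -> None:
    design.frame.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    frame = _read_tsv(path)
    if frame.columns[0] != "sample_id":
        raise ParseError(f"{path}: first column must be 'sample_id'")
    frame = frame.set_index("sample_id")
    for col in frame.columns:
        try:
            frame[col] = pd.to_numeric(frame[col].replace("", np.nan))
        except (ValueError, TypeError):
            raise ParseError(f"{path}: non-numeric phenotype in column {col!r}") from None
    return PhenotypeTable(frame)


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    table.data.rename_axis("sample_id").to_csv(path, sep="\t")
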