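"""Dilution-series performance indicators and rank synthesis.

Six indicators measure how well observed initial target quantities (F0)
track the known inputs of a serial-dilution design, after normalization:

* concentrations are divided by the top concentration (NC, top level = 1);
* each gene's F0 values are divided by the mean F0 of that gene's
  top-concentration replicate group (mean of the top group = 1 exactly).

Indicators (all lower-is-better; resolution's optimum is 1):

1. bias, ratio form   — |mean-F0 ratio between the extreme levels − expected|
2. bias, slope form   — |OLS slope of log10(F0) on log10(NC) − 1|
3. relative error     — mean |(F0 − NC) / NC| over wells
4. coefficient of variation — per replicate group SD/mean × 100%, averaged
5. precision          — within-group sample variance of F0, averaged
6. resolution         — fold-width of the 95% prediction band of the
                        log10(NC)-on-log10(F0) regression, geometric-mean
                        over levels (1 = perfect)

Rank synthesis averages per-indicator ranks across methods and tests for
consistent differences with the Friedman statistic (blocks = indicators,
treatments = methods), with tie correction.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, FormatError, ParameterError

_REL_TOL = 1e-6


@dataclasses.dataclass(frozen=True)
class DilutionDesign:
    """Known concentrations of a serial-dilution experiment."""

    concentration_levels: tuple[float, ...]
    replicates_per_level: int
    expected_extreme_ratio: float
    orientation: str = "high_over_low"

    def __post_init__(self) -> None:
        levels = tuple(float(v) for v in self.concentration_levels)
        if len(levels) < 2:
            raise ParameterError("a dilution design needs at least 2 levels")
        if any(v <= 0 for v in levels):
            raise ParameterError("concentration levels must be positive")
        if any(a <= b for a, b in zip(levels, levels[1:])):
            raise ParameterError("concentration levels must be strictly descending")
        ratios = [a / b for a, b in zip(levels, levels[1:])]
        if any(abs(r / ratios[0] - 1.0) > _REL_TOL for r in ratios):
            raise ParameterError(
                f"consecutive level ratios must be constant, got {ratios}"
            )
        if self.orientation not in ("high_over_low", "low_over_high"):
            raise ParameterError(f"unknown orientation {self.orientation!r}")
        expected = levels[0] / levels[-1]
        if self.orientation == "low_over_high":
            expected = 1.0 / expected
        if abs(self.expected_extreme_ratio / expected - 1.0) > _REL_TOL:
            raise ParameterError(
                f"expected_extreme_ratio {self.expected_extreme_ratio} inconsistent "
                f"with levels/orientation (should be {expected:g})"
            )
        object.__setattr__(self, "concentration_levels", levels)

    @classmethod
    def from_levels(
        cls,
        levels,
        replicates_per_level: int,
        orientation: str = "high_over_low",
    ) -> "DilutionDesign":
        levels = tuple(sorted((float(v) for v in levels), reverse=True))
        expected = levels[0] / levels[-1]
        if orientation == "low_over_high":
            expected = 1.0 / expected
        return cls(levels, replicates_per_level, expected, orientation)

    @property
    def step_ratio(self) -> float:
        return self.concentration_levels[0] / self.concentration_levels[1]


@dataclasses.dataclass
class IndicatorReport:
    """The six indicators for one method on one dilution-series dataset."""

    bias_ratio_dev: float
    bias_slope_dev: float
    mean_relative_error: float
    mean_cv_pct: float
    mean_precision: float
    resolution_fold: float
    per_gene: pd.DataFrame

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "bias_ratio_dev", "bias_slope_dev", "mean_relative_error",
                "mean_cv_pct", "mean_precision", "resolution_fold",
            )
        }
        d["per_gene"] = self.per_gene.to_dict(orient="records")
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def build_f0_table(results, plate) -> pd.DataFrame:
    """Join quantification results with plate concentrations.

    Keeps wells that have both a finite F0 and a known concentration.
    Columns: gene, well_id, concentration, f0.
    """
    conc = {c.well_id: c.known_concentration for c in plate}
    rows = []
    for r in results:
        c = conc.get(r.well_id)
        if c is None or not np.isfinite(r.f0):
            continue
        rows.append(
            {"gene": r.gene, "well_id": r.well_id, "concentration": float(c), "f0": float(r.f0)}
        )
    return pd.DataFrame(rows, columns=["gene", "well_id", "concentration", "f0"])


def _top_concentration(table: pd.DataFrame, design: DilutionDesign | None) -> float:
    if design is not None:
        return design.concentration_levels[0]
    return float(table["concentration"].max())


def _is_level(conc: pd.Series, level: float) -> pd.Series:
    return (conc / level - 1.0).abs() <= _REL_TOL


def normalize_f0(table: pd.DataFrame, design: DilutionDesign | None = None) -> pd.DataFrame:
    """Add NC (concentration / top) and f0_norm (F0 / gene top-group mean).

    After normalization the mean normalized F0 of every gene's top group is
    exactly 1, as is the top NC: both scales share the same maximum.
    """
    if table.empty:
        raise DomainError("empty F0 table")
    top = _top_concentration(table, design)
    out = table.copy()
    out["nc"] = out["concentration"] / top
    out["f0_norm"] = np.nan
    for gene, grp in out.groupby("gene", sort=False):
        top_mask = _is_level(grp["concentration"], top)
        if not top_mask.any():
            raise DomainError(f"gene {gene!r} has no wells at the top concentration")
        top_mean = float(grp.loc[top_mask, "f0"].mean())
        if top_mean <= 0:
            raise DomainError(f"gene {gene!r}: non-positive top-group mean F0")
        out.loc[grp.index, "f0_norm"] = grp["f0"] / top_mean
    return out


def _require_normalized(table: pd.DataFrame) -> None:
    if "nc" not in table.columns or "f0_norm" not in table.columns:
        raise ParameterError("table must be normalized first (see normalize_f0)")


def _per_gene_bias_ratio(table: pd.DataFrame, design: DilutionDesign) -> pd.Series:
    _require_normalized(table)
    hi, lo = design.concentration_levels[0], design.concentration_levels[-1]
    devs = {}
    for gene, grp in table.groupby("gene", sort=False):
        hi_vals = grp.loc[_is_level(grp["concentration"], hi), "f0_norm"]
        lo_vals = grp.loc[_is_level(grp["concentration"], lo), "f0_norm"]
        if hi_vals.empty or lo_vals.empty:
            raise DomainError(f"gene {gene!r}: missing an extreme dilution level")
        ratio = hi_vals.mean() / lo_vals.mean()
        if design.orientation == "low_over_high":
            ratio = 1.0 / ratio
        devs[gene] = abs(ratio - design.expected_extreme_ratio)
    return pd.Series(devs, name="bias_ratio_dev")


def bias_ratio(table: pd.DataFrame, design: DilutionDesign) -> float:
    """Mean over genes of |extreme-level mean-F0 ratio − expected ratio|."""
    return float(_per_gene_bias_ratio(table, design).mean())


def _per_gene_bias_slope(table: pd.DataFrame) -> pd.Series:
    _require_normalized(table)
    devs = {}
    for gene, grp in table.groupby("gene", sort=False):
        if grp["nc"].nunique() < 3:
            raise DomainError(f"gene {gene!r}: need >= 3 dilution levels for slope")
        res = stats.linregress(np.log10(grp["nc"]), np.log10(grp["f0_norm"]))
        devs[gene] = abs(res.slope - 1.0)
    return pd.Series(devs, name="bias_slope_dev")


def bias_slope(table: pd.DataFrame) -> float:
    """Mean over genes of |OLS slope of log10(F0) on log10(NC) − 1|."""
    return float(_per_gene_bias_slope(table).mean())


def _per_gene_relative_error(table: pd.DataFrame) -> pd.Series:
    _require_normalized(table)
    re = (table["f0_norm"] - table["nc"]) / table["nc"]
    return re.abs().groupby(table["gene"], sort=False).mean().rename("mean_abs_re")


def relative_error(table: pd.DataFrame) -> float:
    """Mean |(F0 − NC)/NC| over all dilution-series wells."""
    _require_normalized(table)
    re = (table["f0_norm"] - table["nc"]) / table["nc"]
    return float(re.abs().mean())


def _per_gene_cv(table: pd.DataFrame) -> pd.Series:
    _require_normalized(table)
    out = {}
    for gene, grp in table.groupby("gene", sort=False):
        cvs = []
        for _, lvl in grp.groupby("nc", sort=False):
            if len(lvl) < 2:
                raise DomainError(f"gene {gene!r}: replicate group of size < 2")
            mu = lvl["f0_norm"].mean()
            if mu == 0:
                raise DomainError(f"gene {gene!r}: zero group mean")
            cvs.append(lvl["f0_norm"].std(ddof=1) / mu * 100.0)
        out[gene] = float(np.mean(cvs))
    return pd.Series(out, name="mean_cv_pct")


def coefficient_of_variation(table: pd.DataFrame) -> float:
    """Sample-SD/mean × 100% per replicate group, averaged over levels then genes."""
    return float(_per_gene_cv(table).mean())


def _per_gene_precision(table: pd.DataFrame) -> pd.Series:
    _require_normalized(table)
    out = {}
    for gene, grp in table.groupby("gene", sort=False):
        variances = []
        for _, lvl in grp.groupby("nc", sort=False):
            if len(lvl) < 2:
                raise DomainError(f"gene {gene!r}: replicate group of size < 2")
            variances.append(lvl["f0_norm"].var(ddof=1))
        out[gene] = float(np.mean(variances))
    return pd.Series(out, name="precision")


def precision_within_group(table: pd.DataFrame) -> float:
    """Within-replicate-group sample variance of normalized F0, averaged."""
    return float(_per_gene_precision(table).mean())


def _per_gene_resolution(table: pd.DataFrame, confidence: float) -> pd.Series:
    _require_normalized(table)
    if not 0 < confidence < 1:
        raise ParameterError("confidence must be in (0, 1)")
    out = {}
    for gene, grp in table.groupby("gene", sort=False):
        if grp["nc"].nunique() < 3:
            raise DomainError(f"gene {gene!r}: need >= 3 levels for resolution")
        x = np.log10(grp["f0_norm"].to_numpy())
        y = np.log10(grp["nc"].to_numpy())
        n = x.size
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        dof = n - 2
        s2 = float(resid @ resid) / dof
        if s2 <= 0:
            out[gene] = 1.0
            continue
        s = np.sqrt(s2)
        xbar = x.mean()
        sxx = float(((x - xbar) ** 2).sum())
        tcrit = stats.t.ppf(0.5 + confidence / 2.0, dof)
        log_folds = []
        for _, lvl in grp.groupby("nc", sort=False):
            xl = float(np.log10(lvl["f0_norm"]).mean())
            half = tcrit * s * np.sqrt(1.0 + 1.0 / n + (xl - xbar) ** 2 / sxx)
            log_folds.append(half)
        # fold = 10**half; geometric mean over levels = 10**mean(half)
        out[gene] = float(10.0 ** np.mean(log_folds))
    return pd.Series(out, name="resolution_fold")


def resolution_fold(table: pd.DataFrame, confidence: float = 0.95) -> float:
    """Fold-width of the prediction band of log10(NC) on log10(F0).

    Per gene: the half-width h of the two-sided prediction interval of the
    regression, evaluated at each level's mean log10(F0), is converted to a
    fold 10**h; folds are geometric-mean-averaged over levels, then averaged
    over genes.  Equals 1 exactly in the zero-residual limit.
    """
    return float(_per_gene_resolution(table, confidence).mean())


def compute_indicators(
    f0_table: pd.DataFrame,
    design: DilutionDesign,
    confidence: float = 0.95,
) -> IndicatorReport:
    """All six indicators plus a per-gene detail table."""
    norm = normalize_f0(f0_table, design)
    per_gene = pd.concat(
        [
            _per_gene_bias_ratio(norm, design),
            _per_gene_bias_slope(norm),
            _per_gene_relative_error(norm),
            _per_gene_cv(norm),
            _per_gene_precision(norm),
            _per_gene_resolution(norm, confidence),
        ],
        axis=1,
    ).rename_axis("gene").reset_index()
    return IndicatorReport(
        bias_ratio_dev=bias_ratio(norm, design),
        bias_slope_dev=bias_slope(norm),
        mean_relative_error=relative_error(norm),
        mean_cv_pct=coefficient_of_variation(norm),
        mean_precision=precision_within_group(norm),
        resolution_fold=resolution_fold(norm, confidence),
        per_gene=per_gene,
    )


@dataclasses.dataclass
class RankSynthesis:
    """Per-indicator method ranks with the Friedman consistency test."""

    ranks: pd.DataFrame        # methods x indicators, average ranks for ties
    mean_ranks: pd.Series      # per method
    statistic: float           # tie-corrected Friedman chi-square
    pvalue: float              # chi-square approximation, df = k - 1


def rank_synthesis(
    table: pd.DataFrame,
    directions: Mapping[str, str] | None = None,
) -> RankSynthesis:
    """Rank methods per indicator and aggregate with the Friedman test.

    ``table``: methods (rows, index) x indicators (columns), numeric.
    ``directions``: optional per-column "lower" (default) or "higher";
    higher-is-better columns are negated before ranking so rank 1 is always
    best.  Blocks of the Friedman statistic are the indicators; treatments
    are the methods.  Ties get average ranks; the statistic uses the
    ties-robust form and is 0 by convention for completely tied data.
    """
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ParameterError("rank synthesis needs >= 2 methods and >= 2 indicators")
    values = table.apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        bad = [
            f"{m}/{c}"
            for m in table.index
            for c in table.columns
            if pd.isna(values.loc[m, c])
        ]
        raise FormatError(f"non-numeric indicator cells: {bad}")
    directions = dict(directions or {})
    ranked = {}
    for col in values.columns:
        v = values[col].to_numpy(dtype=float)
        if directions.get(col, "lower") == "higher":
            v = -v
        ranked[col] = stats.rankdata(v, method="average")
    ranks = pd.DataFrame(ranked, index=values.index)

    n, k = ranks.shape[1], ranks.shape[0]  # n blocks (indicators), k methods
    r = ranks.to_numpy(dtype=float)        # k x n
    col_sums = r.sum(axis=1)               # rank sum per method over blocks
    num = (k - 1) * float(((col_sums - n * (k + 1) / 2.0) ** 2).sum())
    den = float((r**2).sum()) - n * k * (k + 1) ** 2 / 4.0
    statistic = 0.0 if den <= 1e-12 else num / den
    pvalue = float(stats.chi2.sf(statistic, k - 1))
    mean_ranks = ranks.mean(axis=1).rename("mean_rank")
    return RankSynthesis(
        ranks=ranks, mean_ranks=mean_ranks, statistic=float(statistic), pvalue=pvalue
    )
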