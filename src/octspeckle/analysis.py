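"""Cohort-level inference for the tonometry study.

Implements the statistical battery applied to a cohort table of per-subject
biometry (CCT, CR, AL, ACD, WTW), age, Generalised Gamma speckle parameters
(GG_a, GG_v, GG_p and the derived ratio v/p) and the measured / corrected
intraocular pressures (IOP_nc, IOP_c):

* simple linear regressions with R-squared, F-test p-value and 95% confidence
  band of the mean response;
* the t-based sample-size formula n = sigma^2 (t_{1-a,N-2} + t_{1-b,N-2})^2 / dmu^2;
* a median split of the cohort on IOP with rank-sum group comparisons;
* a deterministic two-sample Kolmogorov-Smirnov contrast between the GG
  densities implied by each group's mean parameters;
* forward stepwise least-squares selection producing the structural IOP model
  (in the reference cohort: IOP_nc = 0.0248 CCT - 16.534 GG_a + 6.853).

No multiple-testing correction is applied: results are reported per parameter,
matching how such exploratory cohorts are conventionally summarised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import InsufficientDataError, ParameterDomainError, SchemaError
from .gg import GGParams, gg_quantile

logger = logging.getLogger(__name__)

__all__ = [
    "REQUIRED_COLUMNS",
    "RegressionResult",
    "StepwiseModel",
    "SampleSizeSpec",
    "GroupComparison",
    "CohortReport",
    "read_cohort",
    "simple_regression",
    "forward_stepwise",
    "sample_size",
    "median_split",
    "group_compare",
    "compare_group_pdfs",
    "cohort_analysis",
]

REQUIRED_COLUMNS = [
    "AL", "CCT", "ACD", "CR", "WTW", "IOP_c", "IOP_nc", "GG_v", "GG_a", "GG_p", "age",
]

#: Predictors entering the regression battery and the stepwise search.
MACRO_PREDICTORS = ["CCT", "CR", "AL", "ACD", "WTW"]
MICRO_PREDICTORS = ["age", "GG_a", "GG_v", "GG_p", "GG_v_over_p"]


def read_cohort(path) -> pd.DataFrame:
    """Load a cohort table (CSV or XLSX) with the canonical column names.

    Missing required columns raise :class:`~octspeckle.errors.SchemaError`;
    extra columns are kept with a warning.  The derived ratio GG_v_over_p is
    (re)computed from GG_v and GG_p.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    df.columns = [str(c).strip() for c in df.columns]
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(missing)
    extra = set(df.columns) - set(REQUIRED_COLUMNS) - {"subject_id", "GG_v_over_p"}
    if extra:
        logger.warning("ignoring extra cohort columns: %s", sorted(extra))
    df = df.copy()
    df["GG_v_over_p"] = df["GG_v"] / df["GG_p"]
    return df


@dataclass
class RegressionResult:
    """Ordinary least-squares simple regression summary with a 95% band."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    x_grid: np.ndarray = field(repr=False)
    fitted: np.ndarray = field(repr=False)
    band_low: np.ndarray = field(repr=False)
    band_high: np.ndarray = field(repr=False)

    def band_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.x_grid,
                "fit": self.fitted,
                "band_low": self.band_low,
                "band_high": self.band_high,
            }
        )


def simple_regression(x, y, *, n_grid: int = 100) -> RegressionResult:
    """OLS regression of ``y`` on ``x`` with the F-test slope p-value.

    The confidence band is the pointwise 95% interval of the fitted mean
    response over ``n_grid`` equispaced predictor values; it is narrowest at
    the predictor mean and widens away from it.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterDomainError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise InsufficientDataError("simple regression needs n >= 3")
    if np.ptp(x) == 0:
        raise ParameterDomainError("predictor is constant; regression is degenerate")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    grid = np.linspace(x.min(), x.max(), n_grid)
    pred = fit.get_prediction(sm.add_constant(grid))
    ci = pred.conf_int(alpha=0.05)
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        p_value=float(fit.f_pvalue),
        n=int(x.size),
        x_grid=grid,
        fitted=np.asarray(pred.predicted_mean),
        band_low=ci[:, 0],
        band_high=ci[:, 1],
    )


@dataclass
class StepwiseModel:
    """Forward stepwise selection result.

    ``selected`` lists predictor names in entry order; ``coefficients`` map
    those names to the coefficients of the refitted final model and
    ``entry_p_values`` records each predictor's partial-F p-value at entry.
    """

    selected: list[str]
    coefficients: dict[str, float]
    intercept: float
    r_squared: float
    entry_p_values: list[float]
    n: int
    alpha_enter: float

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        out = np.full(len(table), self.intercept)
        for name in self.selected:
            out = out + self.coefficients[name] * table[name].to_numpy(dtype=float)
        return out

    def as_dict(self) -> dict:
        return {
            "selected": self.selected,
            "coefficients": self.coefficients,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "entry_p_values": self.entry_p_values,
            "n": self.n,
            "alpha_enter": self.alpha_enter,
        }


def forward_stepwise(candidates, y, alpha_enter: float = 0.05) -> StepwiseModel:
    """Greedy forward selection by smallest partial-F p-value.

    Starting from the empty model, each step fits every one-variable addition
    and admits the candidate with the smallest partial-F p-value provided it
    is below ``alpha_enter``; the loop stops when no addition qualifies.
    Ties are broken by larger model R-squared, then by name order.  An
    addition that makes the design rank-deficient is skipped with a warning.
    """
    if isinstance(candidates, pd.DataFrame):
        cand = {str(k): candidates[k].to_numpy(dtype=float) for k in candidates.columns}
    else:
        cand = {str(k): np.asarray(v, dtype=float) for k, v in dict(candidates).items()}
    if not cand:
        raise ParameterDomainError("at least one candidate predictor is required")
    y = np.asarray(y, dtype=float)
    n = y.size
    if n <= len(cand) + 1:
        raise InsufficientDataError("need more observations than candidates")

    selected: list[str] = []
    entry_ps: list[float] = []
    current = np.ones((n, 1))
    sst = float(np.sum((y - y.mean()) ** 2))
    while True:
        # stop on a numerically perfect fit: residual p-values are meaningless
        resid = y - current @ np.linalg.lstsq(current, y, rcond=None)[0]
        if sst > 0 and float(np.sum(resid**2)) <= 1e-10 * sst:
            break
        best = None  # (p_value, -r_squared, name, fit)
        for name in sorted(set(cand) - set(selected)):
            X = np.column_stack([current, cand[name]])
            if np.linalg.matrix_rank(X) < X.shape[1]:
                logger.warning("stepwise: skipping collinear candidate %r", name)
                continue
            fit = sm.OLS(y, X).fit()
            p = float(fit.pvalues[-1])  # t-test == partial F for one added column
            key = (round(p, 12), -round(float(fit.rsquared), 12), name)
            if best is None or key < best[0]:
                best = (key, name, p, fit)
        if best is None or best[2] >= alpha_enter:
            break
        _, name, p, fit = best
        selected.append(name)
        entry_ps.append(p)
        current = np.column_stack([current, cand[name]])

    final = sm.OLS(y, current).fit()
    coefs = {name: float(final.params[i + 1]) for i, name in enumerate(selected)}
    return StepwiseModel(
        selected=selected,
        coefficients=coefs,
        intercept=float(final.params[0]),
        r_squared=float(final.rsquared) if selected else 0.0,
        entry_p_values=entry_ps,
        n=int(n),
        alpha_enter=alpha_enter,
    )


@dataclass(frozen=True)
class SampleSizeSpec:
    """Inputs of the t-based sample-size formula.

    ``sigma`` is the SD of the parameter of interest, ``delta_mu`` the mean
    change to detect (same units), ``alpha``/``beta`` the type-I/II error
    rates and ``N`` the reference sample size setting the t degrees of
    freedom (N - 2).  The t quantiles enter one-sided (arguments 1 - alpha
    and 1 - beta), as conventionally printed for this formula.
    """

    sigma: float
    delta_mu: float
    alpha: float = 0.05
    beta: float = 0.01
    N: int = 56

    def __post_init__(self):
        if self.sigma <= 0:
            raise ParameterDomainError("sigma must be positive")
        if self.delta_mu <= 0:
            raise ParameterDomainError("delta_mu must be positive")
        if not (0 < self.alpha < 1 and 0 < self.beta < 1):
            raise ParameterDomainError("alpha and beta must lie in (0, 1)")
        if self.N < 3:
            raise ParameterDomainError("N must be >= 3")


def sample_size(spec: SampleSizeSpec, *, ceil: bool = False) -> float:
    """n = sigma^2 (t(1-alpha, N-2) + t(1-beta, N-2))^2 / delta_mu^2.

    Returns the real-valued requirement; ``ceil=True`` rounds up to the next
    whole subject.
    """
    dof = spec.N - 2
    t_a = stats.t.ppf(1.0 - spec.alpha, dof)
    t_b = stats.t.ppf(1.0 - spec.beta, dof)
    n = spec.sigma**2 * (t_a + t_b) ** 2 / spec.delta_mu**2
    return float(np.ceil(n)) if ceil else float(n)


def median_split(records: pd.DataFrame, key: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split records at the median of ``key``.

    The median uses all values (even n: mean of the two middle values).
    Records strictly below go to group 1 and strictly above to group 2;
    records exactly at the median join group 1 with a logged count.
    """
    if len(records) < 2:
        raise InsufficientDataError("median split needs at least 2 records")
    vals = records[key].to_numpy(dtype=float)
    med = float(np.median(vals))
    at = int(np.count_nonzero(vals == med))
    if at:
        logger.info("median_split: %d record(s) exactly at the median -> group 1", at)
    g1 = records[vals <= med]
    g2 = records[vals > med]
    if len(g2) == 0:
        logger.warning("median_split: group above the median is empty")
    return g1, g2


@dataclass
class GroupComparison:
    """Two-group summary: rank-sum p-value and descriptive statistics."""

    key: str
    p_value: float
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int


def group_compare(group1: pd.DataFrame, group2: pd.DataFrame, key: str) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) comparison of ``key``.

    Uses the normal approximation with tie correction and continuity
    correction, plus per-group mean and SD (ddof=1).
    """
    x = group1[key].to_numpy(dtype=float)
    y = group2[key].to_numpy(dtype=float)
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("each group needs at least 2 records")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return GroupComparison(
        key=key,
        p_value=float(min(res.pvalue, 1.0)),
        mean1=float(np.mean(x)),
        sd1=float(np.std(x, ddof=1)),
        n1=int(x.size),
        mean2=float(np.mean(y)),
        sd2=float(np.std(y, ddof=1)),
        n2=int(y.size),
    )


def compare_group_pdfs(
    params1: GGParams, params2: GGParams, m: int = 28
) -> tuple[float, float]:
    """Two-sample KS contrast between two GG densities.

    A two-sample test needs samples, so each parameter set (typically the
    per-group mean of subject-level GG parameters) is turned into ``m``
    deterministic pseudo-observations at the equispaced mid-quantiles
    (i + 1/2)/m via the GG quantile function; the two pseudo-samples are then
    compared with the two-sample Kolmogorov-Smirnov test.  Returns
    (statistic, p_value).
    """
    if m < 2:
        raise ParameterDomainError("m must be >= 2")
    q = (np.arange(m) + 0.5) / m
    s1 = gg_quantile(q, params1)
    s2 = gg_quantile(q, params2)
    res = stats.ks_2samp(s1, s2)
    return float(res.statistic), float(res.pvalue)


def _scatter_frame(x: np.ndarray, y: np.ndarray, reg: RegressionResult) -> pd.DataFrame:
    """Figure data at the observed points: x, y, fitted line and 95% band."""
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    return pd.DataFrame(
        {
            "x": xs,
            "y": ys,
            "fit": reg.intercept + reg.slope * xs,
            "band_low": np.interp(xs, reg.x_grid, reg.band_low),
            "band_high": np.interp(xs, reg.x_grid, reg.band_high),
        }
    )


@dataclass
class CohortReport:
    """Machine-readable result of the full cohort analysis."""

    n_subjects: int
    regressions: pd.DataFrame           # parameter x {IOP_nc, IOP_c}: slope/R2/p
    cross_regressions: pd.DataFrame     # speckle vs CCT checks
    median: float
    group_comparisons: pd.DataFrame     # per-parameter two-group contrast
    group_iop: dict                     # per-group IOP_nc / IOP_c mean +- SD
    pdf_contrast: dict                  # KS statistic/p for group GG densities
    stepwise: StepwiseModel
    figure_data: dict[str, pd.DataFrame] = field(default_factory=dict, repr=False)

    def as_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "regressions": self.regressions.to_dict(orient="records"),
            "cross_regressions": self.cross_regressions.to_dict(orient="records"),
            "iop_nc_median": self.median,
            "group_comparisons": self.group_comparisons.to_dict(orient="records"),
            "group_iop": self.group_iop,
            "pdf_contrast": self.pdf_contrast,
            "stepwise": self.stepwise.as_dict(),
        }

    def write(self, outdir) -> Path:
        """Write JSON report, CSV tables and per-regression figure data."""
        import json

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(self.as_dict(), indent=2))
        self.regressions.to_csv(outdir / "regressions.csv", index=False)
        self.cross_regressions.to_csv(outdir / "cross_regressions.csv", index=False)
        self.group_comparisons.to_csv(outdir / "group_comparisons.csv", index=False)
        figdir = outdir / "figure_data"
        figdir.mkdir(exist_ok=True)
        for name, frame in self.figure_data.items():
            frame.to_csv(figdir / f"{name}.csv", index=False)
        return outdir


def cohort_analysis(
    records: pd.DataFrame, *, alpha_enter: float = 0.05, pdf_ks_m: int = 28
) -> CohortReport:
    """Run the complete cohort battery and return a structured report.

    Covers: every simple regression of the macro (CCT, CR, AL, ACD, WTW) and
    micro (age, GG_a, GG_v, GG_p, GG_v/p) parameters against both IOP_nc and
    IOP_c; the speckle-vs-CCT cross checks; the IOP_nc median split with
    rank-sum group contrasts and the KS contrast of the group-mean GG
    densities; and forward stepwise selection of the structural IOP model.
    """
    missing = set(REQUIRED_COLUMNS) - set(records.columns)
    if missing:
        raise SchemaError(missing)
    if len(records) < 3:
        raise InsufficientDataError("cohort analysis needs >= 3 complete records")
    df = records.copy()
    df["GG_v_over_p"] = df["GG_v"] / df["GG_p"]

    predictors = MACRO_PREDICTORS + MICRO_PREDICTORS
    rows = []
    figure_data = {}
    for pred in predictors:
        row = {"parameter": pred, "mean": df[pred].mean(), "sd": df[pred].std(ddof=1),
               "min": df[pred].min(), "max": df[pred].max()}
        for target in ("IOP_nc", "IOP_c"):
            reg = simple_regression(df[pred], df[target])
            row[f"r_squared_{target}"] = reg.r_squared
            row[f"p_value_{target}"] = reg.p_value
            row[f"slope_{target}"] = reg.slope
            figure_data[f"{pred}_vs_{target}"] = _scatter_frame(
                df[pred].to_numpy(dtype=float), df[target].to_numpy(dtype=float), reg
            )
        rows.append(row)
    regressions = pd.DataFrame(rows)

    cross_rows = []
    for pred in ("GG_a", "GG_v_over_p"):
        reg = simple_regression(df[pred], df["CCT"])
        cross_rows.append(
            {"parameter": pred, "target": "CCT", "r_squared": reg.r_squared,
             "p_value": reg.p_value, "slope": reg.slope}
        )
        figure_data[f"{pred}_vs_CCT"] = _scatter_frame(
            df[pred].to_numpy(dtype=float), df["CCT"].to_numpy(dtype=float), reg
        )
    cross = pd.DataFrame(cross_rows)

    g1, g2 = median_split(df, "IOP_nc")
    med = float(np.median(df["IOP_nc"]))
    comp_rows = []
    for pred in predictors:
        c = group_compare(g1, g2, pred)
        comp_rows.append(
            {"parameter": pred, "group1_mean": c.mean1, "group1_sd": c.sd1,
             "group2_mean": c.mean2, "group2_sd": c.sd2, "p_value": c.p_value}
        )
    comparisons = pd.DataFrame(comp_rows)
    group_iop = {
        "group1": {t: {"mean": float(g1[t].mean()), "sd": float(g1[t].std(ddof=1))}
                   for t in ("IOP_nc", "IOP_c")},
        "group2": {t: {"mean": float(g2[t].mean()), "sd": float(g2[t].std(ddof=1))}
                   for t in ("IOP_nc", "IOP_c")},
    }

    mean_params = [
        GGParams(a=float(g["GG_a"].mean()), v=float(g["GG_v"].mean()),
                 p=float(g["GG_p"].mean()))
        for g in (g1, g2)
    ]
    ks_stat, ks_p = compare_group_pdfs(*mean_params, m=pdf_ks_m)
    pdf_contrast = {
        "ks_statistic": ks_stat,
        "p_value": ks_p,
        "m": pdf_ks_m,
        "group1_params": mean_params[0].as_dict(),
        "group2_params": mean_params[1].as_dict(),
    }

    step = forward_stepwise(df[predictors], df["IOP_nc"], alpha_enter=alpha_enter)

    return CohortReport(
        n_subjects=int(len(df)),
        regressions=regressions,
        cross_regressions=cross,
        median=med,
        group_comparisons=comparisons,
        group_iop=group_iop,
        pdf_contrast=pdf_contrast,
        stepwise=step,
        figure_data=figure_data,
    )
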