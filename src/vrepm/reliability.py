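"""Test-retest reliability and repeated-measures statistics.

This module is the statistical layer of the pipeline:

* Pearson test-retest correlation matrices across first/second-exposure
  behavioral measures;
* intraclass correlations, two-way mixed model, consistency type, single
  measures — Shrout & Fleiss ICC(3,1) — with 95% F-distribution confidence
  intervals;
* paired t-tests (two-sided);
* split-plot repeated-measures ANOVA (:class:`MixedAnova`) supporting one
  or two within-subject factors crossed with an optional between-subject
  factor, with Greenhouse-Geisser sphericity correction and partial eta
  squared effect sizes;
* a priori power / sample-size computation for the paired t-test from the
  noncentral t distribution.

No multiple-testing correction is applied anywhere: every p-value is
reported raw.  The top-level entry point is :class:`ReliabilityModel`,
whose :meth:`~ReliabilityModel.fit` returns a :class:`ReliabilityResults`
bundling the correlation matrix, per-measure ICCs and per-measure
repeated-exposure ANOVAs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .errors import DesignError, InsufficientDataError

ALPHA = 0.05


# ---------------------------------------------------------------------------
# Pearson test-retest matrix
# ---------------------------------------------------------------------------

def pearson_matrix(table: pd.DataFrame, measures: list[str]) -> pd.DataFrame:
    """Pairwise Pearson r across first/second-exposure measures.

    ``table`` is a long cohort table with ``participant_id`` and ``exposure``
    (1/2) columns; the result is a symmetric matrix over the 2*len(measures)
    variables ``<measure>_1`` / ``<measure>_2`` with unit diagonal.  Cells
    with fewer than 3 complete pairs or a constant variable are NaN.
    """
    wide = table.pivot(index="participant_id", columns="exposure", values=measures)
    cols = [f"{m}_{e}" for m in measures for e in (1, 2)]
    data = {f"{m}_{e}": wide[(m, e)] for m in measures for e in (1, 2)}
    w = pd.DataFrame(data)[cols]
    k = len(cols)
    out = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            xi = w.iloc[:, i]
            xj = w.iloc[:, j]
            ok = xi.notna() & xj.notna()
            if i == j:
                out[i, i] = 1.0
                continue
            if ok.sum() < 3:
                continue
            a, b = xi[ok].to_numpy(), xj[ok].to_numpy()
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                continue
            out[i, j] = out[j, i] = stats.pearsonr(a, b).statistic
    return pd.DataFrame(out, index=cols, columns=cols)


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ICCResult:
    """Two-way mixed, consistency, single-measures intraclass correlation."""

    estimate: float
    ci_low: float
    ci_high: float
    ms_between: float  # MS for subjects
    ms_error: float  # residual (subject x occasion) MS
    n: int
    k: int
    undefined: bool = False


def icc_consistency(scores, confidence: float = 0.95) -> ICCResult:
    """ICC(3,1): consistency of single scores across k fixed occasions.

    ``scores`` is an (n_subjects, k_occasions) array with complete rows.
    The estimate is (MS_subjects - MS_error) / (MS_subjects + (k-1) MS_error)
    from a two-way subjects x occasions decomposition without replication;
    the confidence interval comes from F-distribution bounds on
    MS_subjects / MS_error.  Consistency ignores additive occasion shifts.
    """
    y = np.asarray(scores, dtype=float)
    if y.ndim != 2 or y.shape[1] < 2:
        raise ValueError("scores must be (n_subjects, k>=2 occasions)")
    if np.isnan(y).any():
        raise InsufficientDataError("icc_consistency requires complete rows")
    n, k = y.shape
    if n < 5:
        raise InsufficientDataError("need at least 5 subjects for a stable ICC")
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_rows == 0 and ms_err == 0:
        return ICCResult(math.nan, math.nan, math.nan, 0.0, 0.0, n, k, undefined=True)
    denom = ms_rows + (k - 1) * ms_err
    est = (ms_rows - ms_err) / denom if denom > 0 else math.nan
    if ms_err == 0:
        return ICCResult(est, est, est, ms_rows, 0.0, n, k)
    fstat = ms_rows / ms_err
    df1, df2 = n - 1, (n - 1) * (k - 1)
    a = 1 - (1 - confidence) / 2
    fl = fstat / stats.f.ppf(a, df1, df2)
    fu = fstat * stats.f.ppf(a, df2, df1)
    ci_low = (fl - 1) / (fl + k - 1)
    ci_high = (fu - 1) / (fu + k - 1)
    return ICCResult(est, ci_low, ci_high, ms_rows, ms_err, n, k)


# ---------------------------------------------------------------------------
# Paired t
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p: float
    mean_diff: float
    degenerate: bool = False


def paired_t(x, y) -> PairedTResult:
    """Two-sided paired t-test: one-sample t on the differences x - y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    ok = np.isfinite(x) & np.isfinite(y)
    d = x[ok] - y[ok]
    n = d.size
    if n < 3:
        raise InsufficientDataError("need at least 3 complete pairs")
    sd = d.std(ddof=1)
    if sd == 0 or sd < 1e-12 * max(abs(d.mean()), 1e-300):
        return PairedTResult(math.inf if d.mean() != 0 else 0.0, n - 1,
                             0.0 if d.mean() != 0 else 1.0, float(d.mean()), degenerate=True)
    t = d.mean() / (sd / math.sqrt(n))
    p = 2 * stats.t.sf(abs(t), n - 1)
    return PairedTResult(float(t), n - 1, float(p), float(d.mean()))


# ---------------------------------------------------------------------------
# Split-plot repeated-measures ANOVA
# ---------------------------------------------------------------------------

def _orth_contrast(levels: int) -> np.ndarray:
    """Orthonormal contrast basis orthogonal to the constant (levels x levels-1)."""
    return linalg.helmert(levels).T


class MixedAnova:
    """Repeated-measures ANOVA with one or two within factors and an
    optional between-subject factor (split-plot design).

    Parameters
    ----------
    data : DataFrame
        Long format, one observation per subject x within-cell.
    dv : str
        Dependent-variable column.
    within : list of str
        One or two within-subject factor columns.
    subject : str
        Subject identifier column.
    between : str, optional
        Between-subject factor column (constant within subject).

    Subjects missing any within cell are excluded listwise and listed in
    ``results.excluded_subjects``.  Between-group effects use unweighted
    (Type III) marginal means, so unequal group sizes are handled the way
    standard ANOVA software handles them.
    """

    def __init__(self, data: pd.DataFrame, dv: str, within, subject: str,
                 between: str | None = None) -> None:
        self.data = data
        self.dv = dv
        self.within = list(within) if not isinstance(within, str) else [within]
        if not 1 <= len(self.within) <= 2:
            raise ValueError("one or two within factors supported")
        self.subject = subject
        self.between = between

    @classmethod
    def from_dataframe(cls, data, dv, within, subject, between=None) -> "MixedAnova":
        return cls(data, dv, within, subject, between)

    def _wide(self):
        """Pivot to subjects x cells; drop incomplete subjects listwise."""
        d = self.data.dropna(subset=[self.dv])
        levels = [np.unique(d[f].to_numpy()) for f in self.within]
        wide = d.pivot_table(index=self.subject, columns=self.within, values=self.dv,
                             aggfunc="mean", dropna=False)
        # cell order: first within factor major, second minor
        if len(self.within) == 2:
            cols = pd.MultiIndex.from_product(levels, names=self.within)
        else:
            cols = pd.Index(levels[0], name=self.within[0])
        wide = wide.reindex(columns=cols)
        complete = wide.notna().all(axis=1)
        excluded = list(wide.index[~complete])
        wide = wide[complete]
        if self.between is not None:
            grp = d.groupby(self.subject)[self.between].agg(lambda s: s.iloc[0])
            groups = grp.reindex(wide.index)
        else:
            groups = pd.Series("all", index=wide.index)
        return wide, groups, levels, excluded

    def fit(self) -> "AnovaResults":
        wide, groups, levels, excluded = self._wide()
        y = wide.to_numpy(dtype=float)
        n, m = y.shape
        glev = np.unique(groups.to_numpy())
        ngroups = len(glev)
        if self.between is not None:
            counts = groups.value_counts()
            if (counts < 2).any():
                raise DesignError("each between-group level needs >= 2 subjects")
        if n - ngroups < 1:
            raise DesignError("not enough subjects for error degrees of freedom")

        # effect-coded between design (intercept = unweighted mean of groups)
        x = np.ones((n, ngroups))
        for j, lev in enumerate(glev[:-1]):
            col = np.where(groups.to_numpy() == lev, 1.0,
                           np.where(groups.to_numpy() == glev[-1], -1.0, 0.0))
            x[:, j + 1] = col
        xtx_inv = np.linalg.inv(x.T @ x)
        bhat = xtx_inv @ x.T @ y
        resid = y - x @ bhat
        pooled_cov = (resid.T @ resid) / (n - ngroups)

        a = len(levels[0])
        if len(self.within) == 2:
            b = len(levels[1])
            u_a = np.full((a, 1), 1 / math.sqrt(a))
            u_b = np.full((b, 1), 1 / math.sqrt(b))
            contrasts = {
                self.within[0]: np.kron(_orth_contrast(a), u_b),
                self.within[1]: np.kron(u_a, _orth_contrast(b)),
                f"{self.within[0]}*{self.within[1]}": np.kron(_orth_contrast(a), _orth_contrast(b)),
            }
        else:
            contrasts = {self.within[0]: _orth_contrast(a)}

        rows = []

        def _test(c: np.ndarray, l_rows: np.ndarray, name: str, use_eps: bool) -> None:
            z = y @ c
            bz = xtx_inv @ x.T @ z
            q = c.shape[1]
            lb = l_rows @ bz
            h = lb.T @ np.linalg.inv(l_rows @ xtx_inv @ l_rows.T) @ lb
            e = (z - x @ bz).T @ (z - x @ bz)
            ss_h, ss_e = float(np.trace(h)), float(np.trace(e))
            df1 = q * l_rows.shape[0]
            df2 = q * (n - ngroups)
            if use_eps and q > 1:
                msp = c.T @ pooled_cov @ c
                eps = float(np.trace(msp) ** 2 / (q * np.trace(msp @ msp)))
                eps = min(1.0, max(eps, 1.0 / q))
            else:
                eps = 1.0
            f = (ss_h / df1) / (ss_e / df2) if ss_e > 0 else math.inf
            p_unc = float(stats.f.sf(f, df1, df2))
            p_gg = float(stats.f.sf(f, eps * df1, eps * df2))
            pes = ss_h / (ss_h + ss_e) if (ss_h + ss_e) > 0 else math.nan
            rows.append({"effect": name, "SS": ss_h, "SS_error": ss_e,
                         "df1": df1, "df2": df2, "eps": eps, "F": f,
                         "df1_corr": eps * df1, "df2_corr": eps * df2,
                         "p_unc": p_unc, "p_GG": p_gg, "np2": pes})

        l_int = np.zeros((1, ngroups))
        l_int[0, 0] = 1.0
        if self.between is not None:
            l_grp = np.hstack([np.zeros((ngroups - 1, 1)), np.eye(ngroups - 1)])
            _test(np.full((m, 1), 1 / math.sqrt(m)), l_grp, self.between, use_eps=False)
        for name, c in contrasts.items():
            _test(c, l_int, name, use_eps=True)
            if self.between is not None:
                _test(c, l_grp, f"{name}*{self.between}", use_eps=True)

        table = pd.DataFrame(rows).set_index("effect")
        return AnovaResults(self, table, excluded_subjects=excluded,
                            n_subjects=n, groups=dict(groups.value_counts()))


@dataclass
class AnovaResults:
    """Fitted split-plot ANOVA: one row per effect with SS, (GG-corrected)
    degrees of freedom, F, p and partial eta squared."""

    model: MixedAnova
    table: pd.DataFrame
    excluded_subjects: list = field(default_factory=list)
    n_subjects: int = 0
    groups: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"Repeated-measures ANOVA: {self.model.dv}",
            f"  within: {', '.join(self.model.within)}"
            + (f"; between: {self.model.between}" if self.model.between else ""),
            f"  n = {self.n_subjects} subjects"
            + (f" ({len(self.excluded_subjects)} excluded listwise)"
               if self.excluded_subjects else ""),
            "",
        ]
        t = self.table.copy()
        for _, r in t.iterrows():
            lines.append(
                f"  {r.name:<28s} F({r.df1_corr:.2f}, {r.df2_corr:.2f}) = {r.F:8.3f}"
                f"  p = {r.p_GG:.4f}  np2 = {r.np2:.3f}  eps = {r.eps:.3f}"
            )
        return "\n".join(lines)


def rm_anova(table: pd.DataFrame, dependent: str, within_factors,
             between_factor: str | None = None,
             subject: str = "participant_id") -> AnovaResults:
    """Convenience wrapper: fit a :class:`MixedAnova` and return its results."""
    return MixedAnova(table, dependent, within_factors, subject, between_factor).fit()


# ---------------------------------------------------------------------------
# Power analysis for the paired t-test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PowerSpec:
    """A priori power specification for a paired t-test on mean differences."""

    effect_size_d: float = 0.50
    alpha: float = 0.05
    target_power: float = 0.85
    tails: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.target_power < 1:
            raise ValueError("alpha and target_power must lie in (0, 1)")
        if self.effect_size_d <= 0:
            raise ValueError("effect size d must be positive")
        if self.tails not in (1, 2):
            raise ValueError("tails must be 1 or 2")


def power_paired_t(d: float, n: int, alpha: float = 0.05, tails: int = 2) -> float:
    """Power of the paired t-test at effect size d (Cohen) and n pairs.

    Uses the noncentral t with df = n - 1 and noncentrality d * sqrt(n).
    """
    if n < 2:
        return 0.0
    df = n - 1
    nc = d * math.sqrt(n)
    if tails == 2:
        crit = stats.t.ppf(1 - alpha / 2, df)
        return float(stats.nct.sf(crit, df, nc) + stats.nct.cdf(-crit, df, nc))
    crit = stats.t.ppf(1 - alpha, df)
    return float(stats.nct.sf(crit, df, nc))


def required_n_paired_t(spec: PowerSpec, n_max: int = 10**6) -> int:
    """Smallest n >= 2 whose paired-t power reaches the target."""
    lo, hi = 2, 2
    while power_paired_t(spec.effect_size_d, hi, spec.alpha, spec.tails) < spec.target_power:
        lo = hi
        hi *= 2
        if hi > n_max:
            raise OverflowError(f"target power unreachable below n = {n_max}")
    while lo < hi:
        mid = (lo + hi) // 2
        if power_paired_t(spec.effect_size_d, mid, spec.alpha, spec.tails) >= spec.target_power:
            hi = mid
        else:
            lo = mid + 1
    return hi


# ---------------------------------------------------------------------------
# Top-level reliability model
# ---------------------------------------------------------------------------

DEFAULT_MEASURES = [
    "entries_open",
    "latency_first_open",
    "latency_end_exploration",
    "time_open",
    "total_distance",
    "mean_velocity_closed",
]


class ReliabilityModel:
    """Test-retest reliability of behavioral measures over two exposures.

    Built from a long cohort table (one row per participant x exposure with
    the behavioral measures as columns); :meth:`fit` computes the Pearson
    test-retest matrix, per-measure ICC(3,1) with 95% CI, and a per-measure
    repeated-exposure ANOVA (2-level within factor, optional between factor
    such as the maze version used at second testing).
    """

    def __init__(self, table: pd.DataFrame, measures: list[str] | None = None,
                 between: str | None = None) -> None:
        self.table = table
        self.measures = list(measures) if measures else [
            m for m in DEFAULT_MEASURES if m in table.columns
        ]
        self.between = between
        missing = [m for m in self.measures if m not in table.columns]
        if missing:
            raise ValueError(f"measures not in table: {missing}")

    @classmethod
    def from_dataframe(cls, table, measures=None, between=None) -> "ReliabilityModel":
        return cls(table, measures, between)

    def _paired(self, measure: str) -> np.ndarray:
        wide = self.table.pivot(index="participant_id", columns="exposure", values=measure)
        wide = wide.reindex(columns=[1, 2]).dropna()
        return wide.to_numpy(dtype=float)

    def fit(self, confidence: float = 0.95) -> "ReliabilityResults":
        corr = pearson_matrix(self.table, self.measures)
        icc = {}
        for m in self.measures:
            try:
                icc[m] = icc_consistency(self._paired(m), confidence)
            except InsufficientDataError:
                icc[m] = ICCResult(math.nan, math.nan, math.nan, math.nan,
                                   math.nan, len(self._paired(m)), 2, undefined=True)
        anovas = {}
        for m in self.measures:
            try:
                anovas[m] = rm_anova(self.table, m, ["exposure"], self.between)
            except DesignError:
                anovas[m] = None
        return ReliabilityResults(self, corr, icc, anovas)


class ReliabilityResults:
    """Fitted reliability analysis for one cohort."""

    def __init__(self, model: ReliabilityModel, correlations: pd.DataFrame,
                 icc: dict[str, ICCResult], anovas: dict) -> None:
        self.model = model
        self.correlations = correlations
        self.icc = icc
        self.anovas = anovas

    def icc_frame(self) -> pd.DataFrame:
        rows = []
        for m, r in self.icc.items():
            rows.append({"measure": m, "icc": r.estimate, "ci_low": r.ci_low,
                         "ci_high": r.ci_high, "n": r.n})
        return pd.DataFrame(rows).set_index("measure")

    def summary(self) -> str:
        lines = ["Test-retest reliability (two-way mixed, consistency, single measures)", ""]
        lines.append(f"{'measure':<26s}{'ICC':>7s}{'95% CI':>18s}{'retest r':>10s}")
        for m, r in self.icc.items():
            rr = self.correlations.loc[f"{m}_1", f"{m}_2"]
            lines.append(
                f"{m:<26s}{r.estimate:7.2f}   [{r.ci_low:5.2f}, {r.ci_high:5.2f}]{rr:10.2f}"
            )
        lines.append("")
        lines.append("Repeated-exposure ANOVA per measure (within: exposure"
                     + (f"; between: {self.model.between}" if self.model.between else "")
                     + "):")
        for m, res in self.anovas.items():
            if res is None:
                lines.append(f"  {m:<26s} (not estimable)")
                continue
            r = res.table.loc["exposure"]
            lines.append(
                f"  {m:<26s} F({r.df1_corr:.0f}, {r.df2_corr:.0f}) = {r.F:7.3f}"
                f"  p = {r.p_GG:.3f}  np2 = {r.np2:.3f}"
            )
        return "\n".join(lines)
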