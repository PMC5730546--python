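"""Hill dose-response fitting for acute immobilization data.

The immobilized fraction at concentration ``c`` follows the two-parameter
Hill model

    F(c) = c^h / (EC50^h + c^h),

fitted by binomial maximum likelihood on the observed counts (the assay
exposes small groups, typically n = 15 per concentration, so respecting
the counts matters).  Optimization runs on (log EC50, log h) from three
deterministic starts.  ECx values follow in closed form; nonparametric
bootstrap gives percentile confidence intervals; helpers cover Abbott's
control correction, chip-vs-reference method comparison, and the
ANOVA-plus-t-test workflow for behavioral endpoint tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

__all__ = [
    "DoseResponseData",
    "HillFit",
    "fit_hill",
    "hill_curve",
    "ecx",
    "abbott_correct",
    "bootstrap_ci",
    "BootstrapCI",
    "compare_methods",
    "MethodComparison",
    "behavioural_stats",
    "fit_hill4",
]

CONTROL_MORTALITY_QC = 0.05
_P_CLIP = 1e-10


@dataclass
class DoseResponseData:
    """Immobilization counts per concentration and replicate.

    ``table`` columns: ``concentration``, ``n_exposed``, ``n_immobile``
    and optionally ``replicate``.  Zero-concentration rows are the
    negative controls; their pooled mortality above 5% raises a QC flag.
    """

    table: pd.DataFrame
    units: str = "mg/L"
    qc_flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"concentration", "n_exposed", "n_immobile"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        t = self.table
        if (t["concentration"] < 0).any():
            raise ValueError("concentrations must be >= 0")
        if ((t["n_immobile"] < 0) | (t["n_immobile"] > t["n_exposed"])).any():
            raise ValueError("need 0 <= n_immobile <= n_exposed")
        p0 = self.control_mortality
        if p0 is not None and p0 > CONTROL_MORTALITY_QC:
            self.qc_flags.append(
                f"control mortality {p0:.1%} exceeds {CONTROL_MORTALITY_QC:.0%}"
            )

    @property
    def control_mortality(self) -> float | None:
        ctrl = self.table[self.table["concentration"] == 0]
        if ctrl.empty:
            return None
        return float(ctrl["n_immobile"].sum() / ctrl["n_exposed"].sum())


@dataclass
class HillFit:
    """Fitted two-parameter Hill curve; F(ec50) = 0.5 by construction."""

    ec50: float
    hill_slope: float
    log_likelihood: float
    converged: bool
    method: str = "mle"
    ci_ec50: tuple[float, float] | None = None

    def predict(self, concentration):
        return hill_curve(concentration, self.ec50, self.hill_slope)


def hill_curve(concentration, ec50: float, hill_slope: float):
    """Two-parameter Hill response fraction, exactly 0.5 at ec50."""
    c = np.asarray(concentration, float)
    with np.errstate(divide="ignore"):
        logc = np.log(np.where(c > 0, c, 1.0))
    f = expit(hill_slope * (logc - math.log(ec50)))
    f = np.where(c > 0, f, 0.0)
    return f if f.ndim else float(f)


def _validate_for_fit(data: DoseResponseData) -> pd.DataFrame:
    t = data.table[data.table["concentration"] > 0]
    if t["concentration"].nunique() < 4:
        raise ValueError("need at least 4 distinct positive concentrations")
    k, n = t["n_immobile"].sum(), t["n_exposed"].sum()
    if k == 0 or k == n:
        raise ValueError(
            "degenerate data (no partial response); widen the concentration "
            "range so it brackets the EC50"
        )
    return t


def fit_hill(data: DoseResponseData, method: str = "mle") -> HillFit:
    """Fit the two-parameter Hill model.

    ``method='mle'`` (default) maximizes the binomial likelihood of the
    immobile counts; ``method='ls'`` minimizes squared error of the
    response fractions weighted by group size (for comparison with
    fraction-based curve fits).  Optimization is on (log EC50, log h) with
    three deterministic initializations (slope 0.7, 2 and 5 from an
    interpolated half-response start); the ``converged`` flag reports the
    optimizer's own status.  Control (zero-concentration) rows carry no
    information under the two-parameter model and are excluded — apply
    :func:`abbott_correct` first if control mortality is non-zero.
    """
    t = _validate_for_fit(data)
    c = t["concentration"].to_numpy(float)
    n = t["n_exposed"].to_numpy(float)
    k = t["n_immobile"].to_numpy(float)
    logc = np.log(c)

    # deterministic half-response initialization
    grouped = (
        pd.DataFrame({"logc": logc, "n": n, "k": k})
        .groupby("logc", as_index=False)
        .sum()
    )
    frac = grouped["k"] / grouped["n"]
    lg = grouped["logc"].to_numpy()
    cross = np.nonzero((frac.to_numpy()[:-1] < 0.5) & (frac.to_numpy()[1:] >= 0.5))[0]
    if cross.size:
        i = cross[0]
        f0, f1 = frac.iloc[i], frac.iloc[i + 1]
        w = (0.5 - f0) / (f1 - f0) if f1 > f0 else 0.5
        log_ec50_0 = lg[i] + w * (lg[i + 1] - lg[i])
    else:
        log_ec50_0 = float(np.median(lg))

    if method == "mle":
        def objective(z):
            p = expit(np.exp(z[1]) * (logc - z[0]))
            p = np.clip(p, _P_CLIP, 1 - _P_CLIP)
            return -(k * np.log(p) + (n - k) * np.log1p(-p)).sum()
    elif method == "ls":
        obs = k / n
        def objective(z):
            p = expit(np.exp(z[1]) * (logc - z[0]))
            return (n * (obs - p) ** 2).sum()
    else:
        raise ValueError("method must be 'mle' or 'ls'")

    best = None
    for h0 in (0.7, 2.0, 5.0):
        res = optimize.minimize(
            objective,
            x0=[log_ec50_0, math.log(h0)],
            method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    ec50 = float(np.exp(best.x[0]))
    h = float(np.exp(best.x[1]))
    ll = -float(best.fun) if method == "mle" else float("nan")
    return HillFit(
        ec50=ec50,
        hill_slope=h,
        log_likelihood=ll,
        converged=bool(best.success and np.isfinite(best.fun)),
        method=method,
    )


def ecx(fit: HillFit, x_percent: float) -> float:
    """Effective concentration for x% response: EC50 * (x/(100-x))^(1/h)."""
    if not 0 < x_percent < 100:
        raise ValueError("x_percent must lie in (0, 100)")
    return fit.ec50 * (x_percent / (100.0 - x_percent)) ** (1.0 / fit.hill_slope)


def abbott_correct(data: DoseResponseData) -> DoseResponseData:
    """Abbott's correction for control mortality: (p - p0) / (1 - p0).

    Corrected responses below zero are clipped at zero; the corrected
    counts are real-valued.  Control mortality above 5% raises a QC flag.
    Off by default in analysis workflows — call explicitly when needed.
    """
    p0 = data.control_mortality
    if p0 is None:
        raise ValueError("control group (concentration 0) required")
    if p0 >= 1:
        raise ValueError("control mortality of 100% cannot be corrected")
    t = data.table.copy()
    t["n_immobile"] = t["n_immobile"].astype(float)
    treated = t["concentration"] > 0
    p = t.loc[treated, "n_immobile"] / t.loc[treated, "n_exposed"]
    p_adj = ((p - p0) / (1 - p0)).clip(lower=0.0, upper=1.0)
    t.loc[treated, "n_immobile"] = p_adj * t.loc[treated, "n_exposed"]
    t.loc[~treated, "n_immobile"] = 0.0
    corrected = DoseResponseData(table=t, units=data.units)
    if p0 > CONTROL_MORTALITY_QC:
        warnings.warn(
            f"control mortality {p0:.1%} exceeds the 5% QC limit", stacklevel=2
        )
    return corrected


@dataclass
class BootstrapCI:
    low: float
    high: float
    level: float
    n_resamples: int
    n_failed: int
    reliable: bool


def bootstrap_ci(
    data: DoseResponseData,
    B: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    method: str = "mle",
) -> BootstrapCI:
    """Percentile bootstrap CI for EC50 by resampling replicate rows.

    Rows are resampled with replacement within each concentration
    (stratified, preserving the design).  If more than 20% of resamples
    fail to produce a fit, the interval is flagged unreliable.
    """
    fit_hill(data, method=method)  # must succeed on the full data
    rng = np.random.default_rng(seed)
    t = data.table.reset_index(drop=True)
    groups = [idx.to_numpy() for _, idx in t.groupby("concentration").groups.items()]
    estimates = []
    n_failed = 0
    for _ in range(B):
        rows = np.concatenate(
            [rng.choice(g, size=len(g), replace=True) for g in groups]
        )
        sample = DoseResponseData(t.iloc[rows].reset_index(drop=True), data.units)
        try:
            fit = fit_hill(sample, method=method)
        except ValueError:
            n_failed += 1
            continue
        if not fit.converged or not np.isfinite(fit.ec50):
            n_failed += 1
            continue
        estimates.append(fit.ec50)
    if not estimates:
        raise ValueError("all bootstrap resamples failed")
    lo, hi = np.percentile(estimates, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
    return BootstrapCI(
        low=float(lo),
        high=float(hi),
        level=level,
        n_resamples=B,
        n_failed=n_failed,
        reliable=n_failed <= 0.2 * B,
    )


@dataclass
class MethodComparison:
    pearson_r: float
    r_squared: float
    slope: float
    intercept: float
    p_value: float
    n: int


def compare_methods(points_a, points_b) -> MethodComparison:
    """Pearson correlation and least-squares line between paired assays.

    Used to compare chip-based vs reference (multiwell plate) response
    values at matched concentrations.
    """
    a = np.asarray(points_a, float)
    b = np.asarray(points_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired 1-D arrays required")
    if len(a) < 3:
        raise ValueError("need at least 3 paired points")
    lr = stats.linregress(a, b)
    return MethodComparison(
        pearson_r=float(lr.rvalue),
        r_squared=float(lr.rvalue**2),
        slope=float(lr.slope),
        intercept=float(lr.intercept),
        p_value=float(lr.pvalue),
        n=len(a),
    )


def behavioural_stats(
    endpoint_table: pd.DataFrame,
    value_col: str = "value",
    group_col: str = "concentration",
    time_col: str = "time_h",
    control: float = 0.0,
    adjust: str | None = None,
) -> pd.DataFrame:
    """One-way ANOVA across concentrations plus per-group t-tests vs control.

    Per timepoint: an ANOVA over all concentration groups, then an
    independent two-sample t-test of each concentration against the
    concurrent control.  Raw p-values are reported; Holm adjustment (per
    timepoint) is available via ``adjust='holm'`` but off by default.
    """
    t = endpoint_table
    for col in (value_col, group_col, time_col):
        if col not in t.columns:
            raise ValueError(f"missing column {col!r}")
    counts = t.groupby([time_col, group_col])[value_col].count()
    if (counts < 2).any():
        raise ValueError("need >= 2 replicate chambers per group and timepoint")

    rows = []
    for time_h, sub in t.groupby(time_col):
        groups = {g: v[value_col].to_numpy(float) for g, v in sub.groupby(group_col)}
        if control not in groups:
            raise ValueError(f"no control group ({group_col} == {control})")
        allvals = np.concatenate(list(groups.values()))
        if np.ptp(allvals) == 0:
            anova_p = 1.0  # identical values carry no evidence of a difference
        else:
            anova_p = float(stats.f_oneway(*groups.values()).pvalue)
        ctrl = groups[control]
        tested = sorted(g for g in groups if g != control)
        pvals = [
            1.0
            if np.ptp(np.concatenate([groups[g], ctrl])) == 0
            else float(stats.ttest_ind(groups[g], ctrl).pvalue)
            for g in tested
        ]
        if adjust == "holm":
            from statsmodels.stats.multitest import multipletests

            adj = multipletests(pvals, method="holm")[1]
        elif adjust is None:
            adj = [np.nan] * len(pvals)
        else:
            raise ValueError("adjust must be None or 'holm'")
        for g, p, pa in zip(tested, pvals, adj):
            rows.append(
                {
                    time_col: time_h,
                    group_col: g,
                    "anova_p": anova_p,
                    "t_p": p,
                    "t_p_holm": pa,
                }
            )
    return pd.DataFrame(rows)


def fit_hill4(concentrations, responses):
    """Four-parameter Hill fit for continuous behavioral metrics.

    Fits ``bottom + (top - bottom) * F(c)`` by least squares and returns
    ``(bottom, top, ec50, hill_slope)``.
    """
    c = np.asarray(concentrations, float)
    y = np.asarray(responses, float)
    if len(c) < 5:
        raise ValueError("need at least 5 points for a 4-parameter fit")

    def model(cc, bottom, top, log_ec50, log_h):
        return bottom + (top - bottom) * expit(
            np.exp(log_h) * (np.log(cc) - log_ec50)
        )

    p0 = [float(y.min()), float(y.max()), float(np.log(np.median(c))), 0.0]
    popt, _ = optimize.curve_fit(model, c, y, p0=p0, maxfev=20000)
    bottom, top, log_ec50, log_h = popt
    return float(bottom), float(top), float(np.exp(log_ec50)), float(np.exp(log_h))
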