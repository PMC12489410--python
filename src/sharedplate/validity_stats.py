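"""Relative-validity statistics for two-method dietary comparisons.

The core model is a linear mixed model for nutrient intake per recording
period with a fixed period effect and two random intercepts — one per
participant and one per recording period nested within participant::

    y_ij = mu_period(j) + a_i + b_ij + e_ij,
    a_i ~ N(0, sigma_p^2),  b_ij ~ N(0, sigma_pp^2),
    e_ij ~ N(0, sigma_e^2 / w_ij)

Residual variances are heteroscedastic: the SD of the residuals is
modelled as a (linear or cubic) function of the predicted value, and the
fitted SD function supplies per-row weights w = 1/SD^2 for refitting.
Four candidate models (unweighted; first-iteration linear weights;
second-iteration linear and cubic weights) compete, and the one whose
standardized residuals show the least trend against predicted values is
selected.  Effect sizes are pairwise differences of the selected model's
weighted marginal period means with Wald 95% CIs.

Estimation is REML.  The covariance matrix is block diagonal by
participant with rank-one participant and cell updates, so the likelihood
is evaluated in closed form via nested Sherman–Morrison identities and
grouped sums — no matrix larger than the 3x3 fixed-effect cross-product
is ever factored.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .food_data import CHILD_PANEL, MOTHER_PANEL
from .intake_records import PERIODS

log = logging.getLogger(__name__)

#: Method pairs compared, in reporting order.
PAIRS: tuple[tuple[str, str], ...] = (
    ("visida1", "recall"), ("visida2", "recall"), ("visida1", "visida2"))


# ---------------------------------------------------------------------------
# Bland–Altman


@dataclass
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    spearman_rho: float
    rho_defined: bool
    n_pairs: int


def bland_altman(pairs: Sequence[tuple[float, float]]) -> BlandAltmanResult:
    """Bias and 95% limits of agreement for paired method values (A - B).

    The Spearman correlation of the differences against the pair means
    screens for a trend in the bias; when it is undefined (constant
    differences or means) it is reported as 0 with ``rho_defined=False``.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("Bland-Altman needs at least 3 complete pairs")
    diff = arr[:, 0] - arr[:, 1]
    mean = arr.mean(axis=1)
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    rho_defined = np.ptp(diff) > 0 and np.ptp(mean) > 0
    if rho_defined:
        rho = float(stats.spearmanr(diff, mean).statistic)
        if not np.isfinite(rho):
            rho, rho_defined = 0.0, False
    else:
        rho = 0.0
    return BlandAltmanResult(bias, bias - 1.96 * sd, bias + 1.96 * sd,
                             sd, rho, rho_defined, arr.shape[0])


def bland_altman_plot(pairs: Sequence[tuple[float, float]], path,
                      title: str | None = None) -> BlandAltmanResult:
    """Write a Bland-Altman scatter with bias and limit lines to *path*."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    res = bland_altman(pairs)
    arr = np.asarray(pairs, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(arr.mean(axis=1), arr[:, 0] - arr[:, 1], s=12, alpha=0.6)
    for yv, style in ((res.bias, "-"), (res.loa_low, "--"), (res.loa_high, "--")):
        ax.axhline(yv, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference (A - B)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return res


# ---------------------------------------------------------------------------
# Weighted linear mixed model (REML)


@dataclass
class LMMFit:
    """A fitted (possibly weighted) mixed model on long per-period data."""

    periods: tuple[str, ...]            # period levels present, canonical order
    period_means: dict[str, float]      # weighted marginal means
    cov_means: np.ndarray               # covariance of the marginal means
    var_participant: float
    var_period_within: float
    var_residual: float                 # residual scale; row variance is /weight
    weights: np.ndarray
    fitted: np.ndarray                  # fixed effect + participant intercept BLUP
    fitted_marginal: np.ndarray         # fixed effect only
    residuals: np.ndarray               # observed - fitted
    std_residuals: np.ndarray           # residual / conditional SD
    converged: bool
    n_obs: int
    n_participants: int
    neg2_reml: float

    @property
    def mean_vector(self) -> np.ndarray:
        return np.array([self.period_means[p] for p in self.periods])


def _lmm_terms(theta, y, w, part_idx, cell_idx, cell_part, cell_per,
               per_idx, nper, npart, ncell):
    """All REML building blocks for variance components theta.

    Exploits the structure V_i = vp*J + blockdiag_cells(vpp*J + diag(ve/w))
    through nested Sherman-Morrison identities; every quantity reduces to
    per-cell / per-participant / per-period grouped sums.
    """
    vp, vpp, ve = theta
    d = np.maximum(ve / w, 1e-300)   # diagonal; vpp enters via the cell update
    u = 1.0 / d
    S1c = np.bincount(cell_idx, u, minlength=ncell)
    ecell = 1.0 / (1.0 + vpp * S1c)
    c2 = vpp * ecell
    m = u * ecell[cell_idx]                       # rows of A^{-1} 1
    Q = np.bincount(part_idx, m, minlength=npart)
    g1 = 1.0 + vp * Q
    cp = vp / g1

    uy = u * y
    Cy = np.bincount(cell_idx, uy, minlength=ncell)
    # cells are period-pure, so X' A^{-1} X is diagonal
    t = (np.bincount(per_idx, u, minlength=nper)
         - np.bincount(cell_per, c2 * S1c ** 2, minlength=nper))
    XtAy = (np.bincount(per_idx, uy, minlength=nper)
            - np.bincount(cell_per, c2 * S1c * Cy, minlength=nper))
    yAy = float(uy @ y - c2 @ (Cy * Cy))

    My = np.bincount(part_idx, m * y, minlength=npart)
    MX = np.bincount(part_idx * nper + per_idx, m,
                     minlength=npart * nper).reshape(npart, nper)
    XtVX = np.diag(t) - np.einsum("g,gi,gj->ij", cp, MX, MX)
    XtVy = XtAy - MX.T @ (cp * My)
    yVy = yAy - float(cp @ (My * My))
    logdetV = (float(np.log(d).sum()) + float(np.log1p(vpp * S1c).sum())
               + float(np.log1p(vp * Q).sum()))
    return d, m, Q, g1, XtVX, XtVy, yVy, logdetV


def _neg2_reml(theta, y, w, idx):
    part_idx, cell_idx, cell_part, cell_per, per_idx, nper, npart, ncell = idx
    _d, _m, _Q, _g1, XtVX, XtVy, yVy, logdetV = _lmm_terms(
        theta, y, w, part_idx, cell_idx, cell_part, cell_per,
        per_idx, nper, npart, ncell)
    sign, logdetX = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return 1e30
    try:
        beta = np.linalg.solve(XtVX, XtVy)
    except np.linalg.LinAlgError:
        return 1e30
    val = logdetV + logdetX + (yVy - beta @ XtVy)
    return val if np.isfinite(val) else 1e30


def fit_lmm(data: pd.DataFrame, weights: np.ndarray | None = None) -> LMMFit:
    """REML fit of value ~ period + (1|participant) + (1|period:participant).

    *data* is long: columns ``participant_id``, ``period``, ``value``;
    multiple rows per (participant, period) cell are allowed (e.g. day-level
    data).  *weights* scale the residual variance per row as
    sigma_e^2 / weight.  Non-convergence is reported through the
    ``converged`` flag, never as an exception; degenerate inputs (constant
    values) return a trivial converged fit with zero variance components.
    """
    periods_present = tuple(p for p in PERIODS if p in set(data["period"]))
    y = data["value"].to_numpy(dtype=float)
    n = y.size
    per_map = {p: j for j, p in enumerate(periods_present)}
    per_idx = data["period"].map(per_map).to_numpy(dtype=np.int64)
    part_codes, part_levels = pd.factorize(data["participant_id"])
    part_idx = part_codes.astype(np.int64)
    nper, npart = len(periods_present), len(part_levels)
    cell_key = part_idx * nper + per_idx
    cell_levels, cell_idx = np.unique(cell_key, return_inverse=True)
    ncell = cell_levels.size
    cell_part, cell_per = cell_levels // nper, cell_levels % nper
    w_orig = (np.ones(n) if weights is None
              else np.asarray(weights, dtype=float).copy())
    if np.any(w_orig <= 0) or not np.all(np.isfinite(w_orig)):
        raise ValueError("weights must be positive and finite")
    # normalize by the geometric mean and canonicalize to 9 significant
    # digits: rescaling all weights by a constant then yields a bit-identical
    # optimization problem, so results are exactly scale invariant
    gmean_w = float(np.exp(np.mean(np.log(w_orig))))
    w = w_orig / gmean_w
    mag = 10.0 ** (8.0 - np.floor(np.log10(w)))
    w = np.round(w * mag) / mag
    idx = (part_idx, cell_idx, cell_part, cell_per, per_idx, nper, npart, ncell)

    s = float(y.std())
    if s == 0.0 or n <= nper:
        means = {p: float(y[per_idx == per_map[p]].mean())
                 for p in periods_present}
        zero = np.zeros(n)
        return LMMFit(periods_present, means, np.zeros((nper, nper)),
                      0.0, 0.0, 0.0, w_orig, y.copy(), y.copy(), zero, zero,
                      True, n, npart, 0.0)

    ys = y / s
    wmed = float(np.median(w))
    best = None
    for x0 in ([0.4, 0.3, 0.3 * wmed], [0.05, 0.05, 0.9 * wmed]):
        res = optimize.minimize(
            _neg2_reml, x0, args=(ys, w, idx), method="L-BFGS-B",
            bounds=[(0.0, None), (0.0, None), (1e-12, None)],
            options={"maxiter": 300})
        if best is None or res.fun < best.fun:
            best = res
    theta = np.maximum(best.x, [0.0, 0.0, 1e-12])
    converged = bool(best.success) and best.fun < 1e29

    # reassemble outputs on the original scale
    vp, vpp, ve = (float(v) * s * s for v in theta)
    d, m, Q, g1, XtVX, XtVy, yVy, _ = _lmm_terms(
        (vp, vpp, ve), y, w, *idx[:5], nper, npart, ncell)
    beta = np.linalg.solve(XtVX, XtVy)
    cov = np.linalg.inv(XtVX)
    fitted_marg = beta[per_idx]
    r_marg = y - fitted_marg
    blup_a = vp * np.bincount(part_idx, m * r_marg, minlength=npart) / g1
    fitted = fitted_marg + blup_a[part_idx]
    resid = y - fitted
    cond_sd = np.sqrt(np.maximum(vpp + ve / w, 1e-300))
    means = {p: float(beta[per_map[p]]) for p in periods_present}
    return LMMFit(periods_present, means, cov, vp, vpp, ve * gmean_w, w_orig,
                  fitted, fitted_marg, resid, resid / cond_sd,
                  converged, n, npart, float(best.fun))


# ---------------------------------------------------------------------------
# Residual-SD functions and weights


@dataclass
class VarianceFunction:
    """SD of residuals as a polynomial in the predicted value, floored.

    ``kind`` is ``linear`` (degree 1), ``cubic`` (degree 3) or ``none``
    (no usable function: SD identically 1, i.e. unit weights).  The floor
    keeps the fitted SD strictly positive over any prediction range so
    the implied weights 1/SD^2 stay finite.
    """

    kind: str
    coef: tuple[float, ...]
    floor: float
    coef_se: tuple[float, ...] | None = None

    def sd(self, pred) -> np.ndarray:
        pred = np.asarray(pred, dtype=float)
        if self.kind == "none":
            return np.ones_like(pred)
        raw = np.zeros_like(pred)
        for k, c in enumerate(self.coef):
            raw += c * pred ** k
        return np.maximum(raw, self.floor)


def fit_sd_function(residuals, fitted, kind: str = "linear",
                    floor: float | None = None) -> VarianceFunction:
    """OLS of |residual| on predicted values, as an SD-vs-prediction model.

    ``linear`` regresses on (1, pred); ``cubic`` on (1, pred, pred^2,
    pred^3).  The floor defaults to the larger of the 10th percentile of
    |residuals| and a tiny scale-relative constant.  Constant predicted
    values are a degenerate design and yield ``kind='none'``.
    """
    if kind not in ("linear", "cubic"):
        raise ValueError(f"unknown SD-function kind {kind!r}")
    r = np.abs(np.asarray(residuals, dtype=float))
    p = np.asarray(fitted, dtype=float)
    if r.size < 10:
        raise ValueError("SD-function regression needs >= 10 rows")
    if floor is None:
        floor = max(float(np.percentile(r, 10)), 1e-8 * (1.0 + float(r.mean())))
    if np.ptp(p) == 0.0:
        return VarianceFunction("none", (float(r.mean()),), floor)
    degree = 1 if kind == "linear" else 3
    X = np.vander(p, degree + 1, increasing=True)
    coef, _res, rank, _sv = np.linalg.lstsq(X, r, rcond=None)
    if rank < X.shape[1]:
        return VarianceFunction("none", (float(r.mean()),), floor)
    dof = max(r.size - X.shape[1], 1)
    sigma2 = float(np.sum((r - X @ coef) ** 2)) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = tuple(np.sqrt(np.maximum(np.diag(cov), 0.0)))
    return VarianceFunction(kind, tuple(float(c) for c in coef), floor, se)


def weights_from(varfun: VarianceFunction, fitted) -> np.ndarray:
    """Per-row weights 1/SD(pred)^2; the floor guarantees finiteness."""
    sd = varfun.sd(fitted)
    return 1.0 / (sd * sd)


# ---------------------------------------------------------------------------
# Iterative weighting, model selection, effects


@dataclass
class Candidate:
    """One of the four competing weighting strategies."""

    label: str                      # M0..M3
    description: str
    fit: LMMFit
    varfun: VarianceFunction | None
    trend: float | None = None      # |Spearman rho|, |std resid| vs fitted


def trend_statistic(fit: LMMFit) -> float:
    """|Spearman rho| between |standardized residual| and fitted value.

    A quantitative stand-in for visually judging standardized-residual
    plots: the flatter the spread of standardized residuals across the
    prediction range, the more suitable the weighting.
    """
    a = np.abs(fit.std_residuals)
    if np.ptp(a) == 0.0 or np.ptp(fit.fitted) == 0.0:
        return 0.0
    rho = stats.spearmanr(a, fit.fitted).statistic
    return float(abs(rho)) if np.isfinite(rho) else 0.0


def iterative_weighting(data: pd.DataFrame) -> list[Candidate]:
    """Fit the four candidate models of the weighting procedure.

    M0: unweighted.  M1: weights from a linear SD function of M0's
    residuals.  M2/M3: weights from linear/cubic SD functions of M1's
    residuals (second iteration).  Candidates that cannot be built (base
    fit failed, degenerate SD regression) are simply absent; M0 is always
    returned.
    """
    cands = [Candidate("M0", "no weighting was used", fit_lmm(data), None)]
    m0 = cands[0].fit
    if not m0.converged or m0.n_obs < 10:
        return cands
    vf1 = fit_sd_function(m0.residuals, m0.fitted, "linear")
    if vf1.kind == "none":
        return cands
    m1 = fit_lmm(data, weights_from(vf1, m0.fitted))
    cands.append(Candidate("M1", "linear SD weights, first iteration", m1, vf1))
    if not m1.converged:
        return cands
    for label, kind in (("M2", "linear"), ("M3", "cubic")):
        vf = fit_sd_function(m1.residuals, m1.fitted, kind)
        if vf.kind == "none":
            continue
        fit = fit_lmm(data, weights_from(vf, m1.fitted))
        cands.append(Candidate(label, f"{kind} SD weights, second iteration",
                               fit, vf))
    return cands


def select_model(candidates: Sequence[Candidate]) -> Candidate:
    """Choose the candidate with the most suitable weighting.

    Among converged candidates, minimize the standardized-residual trend
    statistic; ties (and strict non-improvements) go to the earlier
    candidate, i.e. fewer weighting iterations and lower polynomial
    order.  If nothing converged the unweighted model is returned,
    flagged via its own convergence state.
    """
    for c in candidates:
        c.trend = trend_statistic(c.fit) if c.fit.converged else None
    converged = [c for c in candidates if c.fit.converged]
    if not converged:
        return candidates[0]
    best = converged[0]
    for c in converged[1:]:
        if c.trend < best.trend:
            best = c
    return best


@dataclass
class EffectSize:
    """Difference of weighted marginal means for one method pair."""

    pair: str                      # e.g. "visida1-recall"
    estimate: float
    ci_low: float
    ci_high: float
    se: float
    p_omnibus: float               # single Wald test of the period effect


def pairwise_effects(fit: LMMFit, alpha: float = 0.05) -> list[EffectSize]:
    """All pairwise differences of period marginal means with Wald CIs.

    The omnibus p-value is a Wald chi-square test of equality of all
    period means, attached to every pair.
    """
    k = len(fit.periods)
    beta = fit.mean_vector
    cov = fit.cov_means
    if k >= 2:
        C = np.zeros((k - 1, k))
        for i in range(k - 1):
            C[i, i], C[i, i + 1] = 1.0, -1.0
        mid = C @ cov @ C.T
        try:
            stat = float((C @ beta) @ np.linalg.solve(mid, C @ beta))
            p_omni = float(stats.chi2.sf(stat, k - 1))
        except np.linalg.LinAlgError:
            p_omni = float("nan")
    else:
        p_omni = float("nan")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    out = []
    index = {p: i for i, p in enumerate(fit.periods)}
    for a, b in PAIRS:
        if a not in index or b not in index:
            continue
        ia, ib = index[a], index[b]
        est = beta[ia] - beta[ib]
        var = cov[ia, ia] + cov[ib, ib] - 2.0 * cov[ia, ib]
        se = float(np.sqrt(max(var, 0.0)))
        out.append(EffectSize(f"{a}-{b}", float(est), float(est - z * se),
                              float(est + z * se), se, p_omni))
    return out


# ---------------------------------------------------------------------------
# Orchestration over roles and nutrients


@dataclass
class ValidityReport:
    """Per-role-per-nutrient summary table plus model diagnostics."""

    summary: pd.DataFrame
    diagnostics: dict


def run_validity_analysis(period_df: pd.DataFrame,
                          panels: dict[str, Sequence[str]] | None = None,
                          roles: Sequence[str] = ("mother", "child"),
                          alpha: float = 0.05) -> ValidityReport:
    """Full method-comparison analysis, separately per role and nutrient.

    *period_df* is the tidy per-period table (one row per participant and
    period, nutrient columns), already restricted to included
    participants.  For each role x nutrient: Bland-Altman screen per
    method pair, the four-model weighting procedure, model selection and
    pairwise effects.  One nutrient's failure never aborts the rest.
    """
    if panels is None:
        panels = {"mother": MOTHER_PANEL, "child": CHILD_PANEL}
    rows = []
    diagnostics: dict = {}
    for role in roles:
        sub = period_df[period_df["role"] == role]
        if sub.empty:
            continue
        for nutrient in panels.get(role, ()):
            if nutrient not in sub.columns:
                continue
            long = (sub[["participant_id", "period", nutrient]]
                    .rename(columns={nutrient: "value"})
                    .dropna(subset=["value"]).reset_index(drop=True))
            row: dict = {"role": role, "nutrient": nutrient}
            for period in PERIODS:
                vals = long.loc[long["period"] == period, "value"]
                row[f"mean_{period}"] = float(vals.mean()) if len(vals) else np.nan
                row[f"sd_{period}"] = (float(vals.std(ddof=1))
                                       if len(vals) > 1 else np.nan)
                row[f"n_{period}"] = int(len(vals))
            diag: dict = {}
            wide = long.pivot(index="participant_id", columns="period",
                              values="value")
            for a, b in PAIRS:
                if a in wide.columns and b in wide.columns:
                    both = wide[[a, b]].dropna()
                    if len(both) >= 3:
                        diag[f"bland_altman_{a}-{b}"] = bland_altman(
                            list(map(tuple, both.to_numpy())))
            if long["value"].nunique() <= 1:
                row.update(status="degenerate: constant intake values",
                           selected_model=None, weighted=False,
                           p_value=np.nan)
                rows.append(row)
                diagnostics[(role, nutrient)] = diag
                continue
            try:
                candidates = iterative_weighting(long)
                chosen = select_model(candidates)
                effects = pairwise_effects(chosen.fit, alpha=alpha)
            except Exception as exc:            # per-nutrient isolation
                log.exception("analysis failed for %s/%s", role, nutrient)
                row.update(status=f"error: {exc}", selected_model=None,
                           weighted=False, p_value=np.nan)
                rows.append(row)
                diagnostics[(role, nutrient)] = diag
                continue
            row.update(status="ok", selected_model=chosen.label,
                       weighted=chosen.label != "M0",
                       p_value=effects[0].p_omnibus if effects else np.nan)
            for eff in effects:
                key = eff.pair.replace("-", "_minus_")
                row[f"est_{key}"] = eff.estimate
                row[f"lo_{key}"] = eff.ci_low
                row[f"hi_{key}"] = eff.ci_high
            diag["candidates"] = {
                c.label: {"trend": c.trend, "converged": c.fit.converged,
                          "varfun": (None if c.varfun is None else
                                     {"kind": c.varfun.kind,
                                      "coef": list(c.varfun.coef),
                                      "floor": c.varfun.floor})}
                for c in candidates}
            diag["selected"] = chosen.label
            rows.append(row)
            diagnostics[(role, nutrient)] = diag
    return ValidityReport(pd.DataFrame(rows), diagnostics)
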