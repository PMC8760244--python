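"""Classical and multi-regression models of chamber CO2 fluxes.

Ecosystem respiration follows the exponential temperature response

    ER = a exp(b Ta) + eps,                      Q10 = exp(10 b),

and gross primary production the rectangular-hyperbola light response

    GPP = Fmax alpha rs / (Fmax + alpha rs) + eps,

with Fmax, alpha < 0 so GPP <= 0.  The multi-regression family perturbs the
classical parameters with additional drivers (GFC, VWC, Ts, RH, Pr, h, DOY):

    ER  = (a0 + a1 x1 + a2 x2 + ...) exp(b0 Ta) + eps
    GPP = K(rs) (A0 + A1 y1 + ...) + K(rs)^2 (B0 + B1 y1 + ...) + eps,
    K(rs) = F alpha0 rs / (F + alpha0 rs)

Identifiability.  The GPP family is invariant under the one-parameter gauge
(F, alpha0, A, B) -> (cF, c alpha0, A/c, B/c^2): the kernel scales by c and
the blocks absorb it.  Ordinary nonlinear least squares therefore has a flat
direction, and any printed (F, alpha0, A) triple is one representative of an
orbit.  This package fits the identifiable parametrization

    rho = F/alpha0 [W m-2],  P_i = F A_i [umol m-2 s-1],  Q_j = F^2 B_j,

in which GPP = rs/(rho + rs) * (P0 + P1 y1 + ...) + (rs/(rho+rs))^2 (Q0 + ...)
is linear given rho, so the fit reduces to a one-dimensional profile over rho
(variable projection: grid search plus bounded Brent refinement, the linear
block solved exactly at each rho).  ER fits the same way with b0 as the
profiled parameter.  Reported (F, alpha0, A_i) values use the convention that
the A-block averages to 1 over the sample, i.e. F is the light-saturated flux
at the campaign-mean cover and moisture.

Model comparison uses the regression form of the Akaike criterion,
AIC = N log(sum eps_i^2) - 2k with k counting the named parameters plus the
residual variance; explained variance is (var_flux - var_res)/var_flux.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.diagnostic import lilliefors as _lilliefors

DRIVER_POOL = ("GFC", "VWC", "Ts", "RH", "Pr", "h", "DOY")

#: reference irradiance (W/m2) at which the GPP driver responses R_i =
#: P_i * rs_ref/(rho + rs_ref) are reported.  P_i alone trades off against
#: rho (a flat direction of the kernel shape on noisy data); evaluated at a
#: fixed mid-range irradiance the response is stable and comparable across
#: fits.
RS_REF = 400.0

#: units of reported parameters (Table-style conventions)
PARAM_UNITS = {
    "a": "umol/m2/s",
    "b": "1/degC",
    "F": "umol/m2/s",
    "alpha0": "umol/W/s",
    "A": "dimensionless",
    "B": "dimensionless",
    "rho": "W/m2",
    "P": "umol/m2/s",
    "Q": "umol/m2/s",
}


class FitError(RuntimeError):
    """Raised when a model fit cannot be completed; carries the best iterate."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class RankDeficiencyError(FitError):
    """Raised when the linear block is rank deficient; names the offending drivers."""


@dataclass(frozen=True)
class ModelSpec:
    """Which drivers enter the regression.

    target: 'ER' or 'GPP'.  drivers: the linear-block drivers (the x_i of the
    ER prefactor or the y_i of the GPP A-block).  b_drivers: the GPP
    second-order block; None means the block is absent, () means intercept
    only.  classical is the empty spec: ER = a exp(b Ta), GPP = rectangular
    hyperbola with the A-block pinned to 1.
    """

    target: str
    drivers: tuple[str, ...] = ()
    b_drivers: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.target not in ("ER", "GPP"):
            raise ValueError(f"target must be 'ER' or 'GPP', got {self.target!r}")
        if len(set(self.drivers)) != len(self.drivers):
            raise ValueError("duplicate drivers in linear block")
        if self.b_drivers is not None:
            if self.target != "GPP":
                raise ValueError("b_drivers only apply to GPP models")
            if len(set(self.b_drivers)) != len(self.b_drivers):
                raise ValueError("duplicate drivers in B block")

    @property
    def classical(self) -> bool:
        return not self.drivers and self.b_drivers is None

    @property
    def k(self) -> int:
        """Parameter count including the residual variance (paper-style:
        named parameters, even though one GPP combination is a gauge)."""
        if self.target == "ER":
            return 2 + len(self.drivers) + 1  # a0..am, b0, + sigma2
        if self.classical:
            return 2 + 1  # F, alpha0, + sigma2
        k = 2 + 1 + len(self.drivers)  # F, alpha0, A0..Am
        if self.b_drivers is not None:
            k += 1 + len(self.b_drivers)
        return k + 1

    def describe(self) -> str:
        extras = "+".join(self.drivers) if self.drivers else "classical"
        tail = "" if self.b_drivers is None else f"|B:{'+'.join(self.b_drivers) or '1'}"
        return f"{self.target}[{extras}{tail}]"


@dataclass
class FitResult:
    spec: ModelSpec
    params: dict          # reported parameters (a0.., b0 / F, alpha0, A0..)
    ident_params: dict    # identifiable parametrization (b0,a.. / rho, P..)
    residuals: np.ndarray
    fitted: np.ndarray
    sigma2_expl: float
    aic: float
    n: int
    k: int
    lilliefors_p: float | None = None
    bartlett_p: float | None = None
    pruned: tuple = ()
    prune_pvalues: dict = field(default_factory=dict)

    @property
    def sse(self) -> float:
        return float(np.sum(self.residuals**2))


@dataclass(frozen=True)
class Q10Value:
    q10: float
    b: float


def q10_from_b(b: float) -> Q10Value:
    """Q10 = exp(10 b) of the exponential temperature response."""
    return Q10Value(q10=float(np.exp(10.0 * b)), b=float(b))


# ---------------------------------------------------------------------------
# model evaluation


def eval_er_classical(ta, a, b):
    """ER = a exp(b Ta)."""
    return a * np.exp(b * np.asarray(ta, dtype=float))


def eval_gpp_classical(rs, f_max, alpha):
    """GPP = Fmax alpha rs / (Fmax + alpha rs); Fmax, alpha < 0 by convention."""
    rs = np.asarray(rs, dtype=float)
    denom = f_max + alpha * rs
    if np.any(np.isclose(denom, 0.0)):
        raise ZeroDivisionError("light-response denominator Fmax + alpha*rs vanishes")
    return f_max * alpha * rs / denom


def eval_er_multi(data, params, spec: ModelSpec):
    """ER = (a0 + a1 x1 + ...) exp(b0 Ta) with params {'a0','a1',..,'b0'}."""
    pre = np.full(len(data), params["a0"], dtype=float)
    for i, d in enumerate(spec.drivers, start=1):
        pre = pre + params[f"a{i}"] * _col(data, d)
    return pre * np.exp(params["b0"] * _col(data, "Ta"))


def eval_gpp_multi(data, params, spec: ModelSpec):
    """GPP = K (A0 + A1 y1 + ...) + K^2 (B0 + ...), K the hyperbolic kernel."""
    rs = _col(data, "rs")
    denom = params["F"] + params["alpha0"] * rs
    if np.any(np.isclose(denom, 0.0)):
        raise ZeroDivisionError("light-response denominator F + alpha0*rs vanishes")
    kernel = params["F"] * params["alpha0"] * rs / denom
    if spec.classical:
        return kernel
    ablock = np.full(len(data), params["A0"], dtype=float)
    for i, d in enumerate(spec.drivers, start=1):
        ablock = ablock + params[f"A{i}"] * _col(data, d)
    out = kernel * ablock
    if spec.b_drivers is not None:
        bblock = np.full(len(data), params["B0"], dtype=float)
        for i, d in enumerate(spec.b_drivers, start=1):
            bblock = bblock + params[f"B{i}"] * _col(data, d)
        out = out + kernel**2 * bblock
    return out


def _col(data, name) -> np.ndarray:
    if name not in data.columns:
        raise KeyError(f"driver {name!r} missing from records")
    return data[name].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# fitting (variable projection over the single nonlinear parameter)


def _design(data, spec: ModelSpec, theta: float) -> tuple[np.ndarray, list[str]]:
    n = len(data)
    if spec.target == "ER":
        carrier = np.exp(theta * _col(data, "Ta"))
        cols = [carrier]
        names = ["a0"]
        for i, d in enumerate(spec.drivers, start=1):
            cols.append(carrier * _col(data, d))
            names.append(f"a{i}")
    else:
        rs = _col(data, "rs")
        kernel = rs / (theta + rs)  # theta = rho = F/alpha0 > 0
        cols = [kernel]
        names = ["P0"]
        for i, d in enumerate(spec.drivers, start=1):
            cols.append(kernel * _col(data, d))
            names.append(f"P{i}")
        if spec.b_drivers is not None:
            cols.append(kernel**2)
            names.append("Q0")
            for i, d in enumerate(spec.b_drivers, start=1):
                cols.append(kernel**2 * _col(data, d))
                names.append(f"Q{i}")
    return np.column_stack(cols), names


def _check_rank(data, spec: ModelSpec) -> None:
    """Reject constant or collinear driver columns, naming offenders."""
    all_drivers = list(spec.drivers) + list(spec.b_drivers or ())
    bad = [d for d in all_drivers if np.std(_col(data, d)) == 0]
    if bad:
        raise RankDeficiencyError(f"constant driver column(s): {', '.join(sorted(set(bad)))}")
    x, names = _design(data, spec, 0.05 if spec.target == "ER" else 100.0)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        corr = np.corrcoef(x, rowvar=False)
        pairs = [
            f"{names[i]}~{names[j]}"
            for i in range(len(names))
            for j in range(i + 1, len(names))
            if abs(corr[i, j]) > 1.0 - 1e-10
        ]
        raise RankDeficiencyError(
            "rank-deficient design; collinear terms: " + (", ".join(pairs) or "unidentified")
        )


def _profile_sse(theta, data, spec, y):
    x, _ = _design(data, spec, theta)
    coef, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    return float(resid @ resid), coef


def _fit_varpro(data, spec: ModelSpec, y: np.ndarray, grid_size: int = 41):
    """Profile the nonlinear parameter on a grid, refine with bounded Brent."""
    if spec.target == "ER":
        grid = np.linspace(-0.3, 0.6, grid_size)
        transform = lambda t: t  # noqa: E731
    else:
        grid = np.linspace(np.log(1.0), np.log(2.0e4), grid_size)
        transform = np.exp

    sse = np.array([_profile_sse(transform(t), data, spec, y)[0] for t in grid])
    if not np.all(np.isfinite(sse)):
        raise FitError("non-finite residual sum during profiling")
    i = int(np.argmin(sse))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid_size - 1)]
    res = optimize.minimize_scalar(
        lambda t: _profile_sse(transform(t), data, spec, y)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-11},
    )
    theta = transform(res.x if res.fun <= sse[i] else grid[i])
    _, coef = _profile_sse(theta, data, spec, y)
    return theta, coef


def _report_params(data, spec: ModelSpec, theta: float, coef: np.ndarray):
    """Map the identifiable estimate to reported (table-style) parameters."""
    _, names = _design(data, spec, theta)
    if spec.target == "ER":
        ident = {"b0": theta, **dict(zip(names, coef))}
        return dict(ident), ident
    ident = {"rho": theta, **dict(zip(names, coef))}
    kernel_ref = RS_REF / (theta + RS_REF)
    for nm, c in zip(names, coef):
        if nm.startswith("P"):
            ident["R" + nm[1:]] = c * kernel_ref
    if spec.classical:
        f = coef[0]
        return {"F": f, "alpha0": f / theta}, ident
    # gauge convention: A-block sample mean = 1  =>  F = mean linear block
    p_cols = [c for c, nm in zip(coef, names) if nm.startswith("P")]
    block = np.full(len(data), p_cols[0], dtype=float)
    for pi, d in zip(p_cols[1:], spec.drivers):
        block = block + pi * _col(data, d)
    f = float(block.mean())
    if f == 0.0:
        f = p_cols[0] if p_cols[0] != 0 else 1.0  # degenerate zero-flux data
    params = {"F": f, "alpha0": f / theta}
    for nm, c in zip(names, coef):
        if nm.startswith("P"):
            params["A" + nm[1:]] = c / f
        elif nm.startswith("Q"):
            params["B" + nm[1:]] = c / f**2
    return params, ident


def fit_model(
    data: pd.DataFrame,
    spec: ModelSpec,
    diagnostics: bool = True,
    n_groups: int = 4,
    grid_size: int = 41,
    check_rank: bool = True,
) -> FitResult:
    """Unweighted nonlinear least squares via variable projection.

    Raises FitError on non-convergence (carrying the best iterate) and
    RankDeficiencyError when driver columns are constant or collinear.
    ``check_rank=False`` skips the collinearity screen (used by permutation
    loops that refit the same design with shuffled rows).
    """
    n = len(data)
    k = spec.k
    if n <= k:
        raise FitError(f"n={n} must exceed parameter count k={k}")
    if check_rank:
        _check_rank(data, spec)
    y = _col(data, spec.target)
    theta, coef = _fit_varpro(data, spec, y, grid_size=grid_size)
    x, _ = _design(data, spec, theta)
    fitted = x @ coef
    residuals = y - fitted
    params, ident = _report_params(data, spec, theta, coef)

    result = FitResult(
        spec=spec,
        params=params,
        ident_params=ident,
        residuals=residuals,
        fitted=fitted,
        sigma2_expl=explained_variance(y, residuals),
        aic=aic(residuals, k),
        n=n,
        k=k,
    )
    if diagnostics and n >= 2 * n_groups and n >= 10:
        result.lilliefors_p, result.bartlett_p = residual_diagnostics(result, n_groups)
    return result


# ---------------------------------------------------------------------------
# statistics


def explained_variance(flux_values, residuals) -> float:
    """(var_flux - var_res) / var_flux."""
    flux = np.asarray(flux_values, dtype=float)
    var_flux = flux.var(ddof=1)
    if var_flux == 0:
        raise ValueError("zero flux variance: explained variance undefined")
    var_res = np.asarray(residuals, dtype=float).var(ddof=1)
    return float((var_flux - var_res) / var_flux)


def aic(residuals, k: int) -> float:
    """Regression AIC = N log(sum eps^2) - 2k (natural log), k including the
    residual variance."""
    eps = np.asarray(residuals, dtype=float)
    sse = float(np.sum(eps**2))
    if sse <= 0:
        raise ValueError("zero residual sum of squares: AIC log pole")
    return len(eps) * float(np.log(sse)) - 2.0 * k


def residual_diagnostics(fit: FitResult, n_groups: int = 4):
    """(Lilliefors p, Bartlett p) for residual normality and homoscedasticity.

    Bartlett groups the residuals into n_groups equal-size bins ordered by
    fitted value; identically-distributed degenerate groups (all variances
    zero) give statistic 0, p = 1.
    """
    resid = fit.residuals
    if len(resid) < 10:
        raise ValueError("diagnostics need at least 10 residuals")
    if n_groups < 2:
        raise ValueError("need at least 2 groups for Bartlett's test")
    groups = [resid[idx] for idx in np.array_split(np.argsort(fit.fitted), n_groups)]
    if any(len(g) < 2 for g in groups):
        raise ValueError("a Bartlett group has fewer than 2 members")
    _, lp = _lilliefors(resid, dist="norm")
    if all(np.var(g) == 0 for g in groups):
        bp = 1.0
    else:
        _, bp = stats.bartlett(*groups)
    return float(lp), float(bp)


# ---------------------------------------------------------------------------
# driver screening, pruning, selection, attribution


@dataclass
class ScreenResult:
    table: pd.DataFrame            # x, y, r, p, excluded
    forbidden_pairs: set           # frozensets of driver names

    def admissible(self, pair) -> bool:
        return frozenset(pair) not in self.forbidden_pairs


def partial_correlation_screen(data: pd.DataFrame, candidates, alpha: float = 0.05) -> ScreenResult:
    """Pairwise partial correlations among candidate drivers, each pair
    controlling for all remaining candidates; significantly correlated pairs
    (p < alpha) are forbidden from co-occurring in one model."""
    import pingouin as pg

    candidates = list(candidates)
    if len(candidates) < 3:
        raise ValueError("screen needs at least 3 candidate drivers")
    for c in candidates:
        if np.std(_col(data, c)) == 0:
            raise np.linalg.LinAlgError(f"singular candidate set: {c!r} is constant")
    rows = []
    forbidden = set()
    for i, xv in enumerate(candidates):
        for yv in candidates[i + 1:]:
            # a covariate numerically identical to x or y makes the partial
            # correlation undefined; drop it from the conditioning set
            covar = [
                c
                for c in candidates
                if c not in (xv, yv)
                and not np.allclose(_col(data, c), _col(data, xv))
                and not np.allclose(_col(data, c), _col(data, yv))
            ]
            if np.allclose(_col(data, xv), _col(data, yv)):
                r, p = 1.0, 0.0
            elif not covar:
                from scipy import stats as _st

                r, p = map(float, _st.pearsonr(_col(data, xv), _col(data, yv)))
            else:
                out = pg.partial_corr(data=data, x=xv, y=yv, covar=covar)
                pcol = "p_val" if "p_val" in out.columns else "p-val"
                r, p = float(out["r"].iloc[0]), float(out[pcol].iloc[0])
            excluded = p < alpha
            if excluded:
                forbidden.add(frozenset((xv, yv)))
            rows.append({"x": xv, "y": yv, "r": r, "p": p, "excluded": excluded})
    return ScreenResult(table=pd.DataFrame(rows), forbidden_pairs=forbidden)


def prune_parameters(
    data: pd.DataFrame,
    fit: FitResult,
    alpha: float = 0.05,
    n_shuffles: int = 999,
    seed: int = 0,
) -> FitResult:
    """Iteratively remove the least-significant extra driver (randomization
    p > alpha), refit, repeat.  The classical kernel (a0, b0 / F, alpha0 and
    the A-block intercept) is never pruned."""
    from .randomization import coefficient_significance

    spec = fit.spec
    current = fit
    pruned: list[str] = []
    pvals: dict[str, float] = {}
    while True:
        extras = _prunable_terms(current.spec)
        if not extras:
            break
        term_p = {}
        for term, driver in extras:
            nd = coefficient_significance(
                data, current.spec, term, n_shuffles=n_shuffles, seed=seed
            )
            term_p[(term, driver)] = nd.p_two_tailed
        worst, worst_p = max(term_p.items(), key=lambda kv: kv[1])
        pvals.update({t: p for (t, _), p in term_p.items()})
        if worst_p <= alpha:
            break
        new_spec = _drop_term(current.spec, worst)
        pruned.append(worst[0])
        current = fit_model(data, new_spec)
    current = replace(
        current, pruned=tuple(pruned), prune_pvalues={**pvals}
    )
    return current


def _prunable_terms(spec: ModelSpec):
    terms = []
    if spec.target == "ER":
        terms += [(f"a{i}", d) for i, d in enumerate(spec.drivers, start=1)]
    else:
        terms += [(f"A{i}", d) for i, d in enumerate(spec.drivers, start=1)]
        if spec.b_drivers is not None:
            terms += [(f"B{i}", d) for i, d in enumerate(spec.b_drivers, start=1)]
            terms += [("B0", None)]
    return terms


def _drop_term(spec: ModelSpec, term_driver) -> ModelSpec:
    term, driver = term_driver
    if term.startswith("a") or term.startswith("A"):
        return replace(spec, drivers=tuple(d for d in spec.drivers if d != driver))
    if term == "B0" and not spec.b_drivers:
        return replace(spec, b_drivers=None)
    b = tuple(d for d in spec.b_drivers if d != driver)
    return replace(spec, b_drivers=b)


def select_model(
    data: pd.DataFrame,
    candidate_specs,
    prune_alpha: float | None = None,
    n_shuffles: int = 999,
    seed: int = 0,
):
    """Fit every candidate, rank by AIC ascending (ties broken by fewer
    parameters, then lexicographic driver names), then prune the front
    runner and re-rank.  Pruning only the AIC-best candidate keeps the
    randomization refits affordable; a pruned front runner is a sub-spec of
    itself, so the selected model is unchanged.  Returns (ranked fits,
    failures) where failures maps spec description to the error message."""
    fits, failures = [], {}
    for spec in candidate_specs:
        try:
            fits.append(fit_model(data, spec))
        except (FitError, ValueError, KeyError) as exc:
            failures[spec.describe()] = str(exc)
    if not fits:
        raise FitError("all candidate specifications failed: " + "; ".join(failures.values()))
    key = lambda f: (f.aic, f.k, tuple(sorted(f.spec.drivers)))  # noqa: E731
    fits.sort(key=key)
    if prune_alpha is not None:
        fits[0] = prune_parameters(
            data, fits[0], alpha=prune_alpha, n_shuffles=n_shuffles, seed=seed
        )
        fits.sort(key=key)
    return fits, failures


def driver_weight(data: pd.DataFrame, best_spec: ModelSpec) -> pd.DataFrame:
    """Per-driver enhancement of explained variance over the classical model.

    For each extra driver d of the selected model, refit classical + d alone
    and report Delta sigma2_expl = sigma2(classical + d) - sigma2(classical).
    """
    classical = ModelSpec(target=best_spec.target)
    base = fit_model(data, classical, diagnostics=False)
    rows = []
    for d in best_spec.drivers:
        try:
            one = fit_model(data, replace(classical, drivers=(d,)), diagnostics=False)
            rows.append(
                {"driver": d, "delta_sigma2_expl": one.sigma2_expl - base.sigma2_expl, "error": ""}
            )
        except FitError as exc:
            rows.append({"driver": d, "delta_sigma2_expl": np.nan, "error": str(exc)})
    return pd.DataFrame(rows, columns=["driver", "delta_sigma2_expl", "error"])
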