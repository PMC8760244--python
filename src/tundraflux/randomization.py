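"""Shuffle-based significance tests.

Three randomization tests back all inference in the pipeline:

* difference of group means (two series pooled and reassigned, preserving
  the original group sizes);
* significance of a regression coefficient (the driver column is permuted
  across records, the model refit, the coefficient re-estimated);
* difference of a model parameter fitted on two series (records mixed across
  the series, both models refit).

All tests are double-tailed on |statistic| and use the add-one estimator
p = (1 + #{|draw| >= |observed|}) / (n_shuffles + 1), which can never return
zero.  Whenever the total number of distinct group assignments does not
exceed 10,000, the mean-difference test switches to exact enumeration
(p = #{|draw| >= |observed|}/n_arrangements, which includes the identity
assignment and is therefore also positive).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .models import FitError, ModelSpec, fit_model

EXHAUSTIVE_LIMIT = 10_000


@dataclass
class NullDistribution:
    observed: float
    draws: np.ndarray
    n_shuffles: int
    seed: int | None
    p_two_tailed: float
    statistic: str = ""
    exhaustive: bool = False


def _pvalue(observed: float, draws: np.ndarray, exhaustive: bool) -> float:
    c = int(np.sum(np.abs(draws) >= abs(observed) - 1e-12))
    if exhaustive:
        return c / len(draws)
    return (1 + c) / (len(draws) + 1)


def mean_difference_test(series_a, series_b, n_shuffles: int = 10_000, seed: int | None = None) -> NullDistribution:
    """Randomization test for a difference of means, double-tailed.

    Pooled values are reassigned to two groups of the original sizes each
    shuffle; exact enumeration replaces random shuffling when the number of
    arrangements is at most 10,000.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both series must be non-empty")
    if n_shuffles < 100:
        import warnings

        warnings.warn(f"n_shuffles={n_shuffles} is small; p-values will be coarse")
    observed = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size

    if comb(n, na) <= EXHAUSTIVE_LIMIT:
        from itertools import combinations

        total = pooled.sum()
        draws = np.array(
            [
                (s := pooled[list(idx)].sum()) / na - (total - s) / (n - na)
                for idx in combinations(range(n), na)
            ]
        )
        return NullDistribution(
            observed=float(observed),
            draws=draws,
            n_shuffles=len(draws),
            seed=seed,
            p_two_tailed=_pvalue(observed, draws, exhaustive=True),
            statistic="mean_difference",
            exhaustive=True,
        )

    rng = np.random.default_rng(seed)
    draws = np.empty(n_shuffles)
    for i in range(n_shuffles):
        perm = rng.permutation(pooled)
        draws[i] = perm[:na].mean() - perm[na:].mean()
    return NullDistribution(
        observed=float(observed),
        draws=draws,
        n_shuffles=n_shuffles,
        seed=seed,
        p_two_tailed=_pvalue(observed, draws, exhaustive=False),
        statistic="mean_difference",
    )


def _coefficient_driver(spec: ModelSpec, coefficient: str) -> str:
    """Map a coefficient name (a1, A2, B1, ...) to its driver column."""
    kind, idx = coefficient[0], coefficient[1:]
    if not idx.isdigit() or int(idx) < 1:
        raise ValueError(f"{coefficient!r} is not a testable extra-driver coefficient")
    i = int(idx)
    pool = spec.b_drivers if kind == "B" else spec.drivers
    if kind == "a" and spec.target != "ER":
        raise ValueError("a-coefficients belong to ER models")
    if kind in ("A", "B") and spec.target != "GPP":
        raise ValueError("A/B-coefficients belong to GPP models")
    if pool is None or i > len(pool):
        raise ValueError(f"coefficient {coefficient!r} not present in spec {spec.describe()}")
    return pool[i - 1]


def _batched_coefficient_estimates(records, spec, coefficient, perms, grid_size=41):
    """Profile-fit the model for a batch of row permutations of one driver
    column and return the coefficient estimate for each.

    Same estimator as models.fit_model (variable projection over the single
    nonlinear parameter), but the grid sweep and linear solves run across
    all permutations at once, with a parabolic (3-point) refinement of the
    profiled parameter in place of the scalar Brent polish.
    """
    from .models import _col

    n = len(records)
    y = _col(records, spec.target)
    driver = _coefficient_driver(spec, coefficient)
    kind = coefficient[0]
    cidx = int(coefficient[1:])

    if spec.target == "ER":
        carrier_of = lambda th: np.exp(np.multiply.outer(th, _col(records, "Ta")))  # noqa: E731
        grid = np.linspace(-0.3, 0.6, grid_size)
    else:
        rs = _col(records, "rs")
        # profile in log(rho) space throughout
        carrier_of = lambda th: rs / (np.exp(th)[..., None] + rs)  # noqa: E731
        grid = np.linspace(np.log(1.0), np.log(2.0e4), grid_size)

    lin_cols = [np.ones(n)] + [_col(records, d) for d in spec.drivers]
    quad_cols = (
        [np.ones(n)] + [_col(records, d) for d in (spec.b_drivers or ())]
        if spec.b_drivers is not None
        else []
    )
    k_lin, k_quad = len(lin_cols), len(quad_cols)
    k = k_lin + k_quad
    col_block, col_off = ("quad", k_lin) if kind == "B" else ("lin", 0)
    j = col_off + cidx  # intercepts sit at offset 0 of each block

    perm_vals = _col(records, driver)[perms]  # (P, n)
    p_count = perms.shape[0]

    def _designs(carrier):
        # carrier: (P, n) or (n,) broadcastable
        c = np.broadcast_to(carrier, (p_count, n))
        d = np.empty((p_count, n, k))
        for m, colv in enumerate(lin_cols):
            d[:, :, m] = c * colv
        if k_quad:
            c2 = c * c
            for m, colv in enumerate(quad_cols):
                d[:, :, k_lin + m] = c2 * colv
        if col_block == "lin":
            d[:, :, j] = c * perm_vals
        else:
            d[:, :, j] = (c * c) * perm_vals
        return d

    def _solve(d):
        xtx = np.einsum("pnk,pnl->pkl", d, d)
        xty = np.einsum("pnk,n->pk", d, y)
        try:
            coef = np.linalg.solve(xtx, xty[..., None])[..., 0]
        except np.linalg.LinAlgError:
            coef = np.einsum("pkl,pl->pk", np.linalg.pinv(xtx), xty)
        sse = y @ y - np.einsum("pk,pk->p", coef, xty)
        return coef, sse

    sse_grid = np.empty((p_count, grid_size))
    for gi, th in enumerate(grid):
        carrier = carrier_of(np.full(1, th))[0]
        _, sse_grid[:, gi] = _solve(_designs(carrier))

    best = np.argmin(sse_grid, axis=1)
    # parabolic vertex on the uniform grid; endpoints stay put
    h = grid[1] - grid[0]
    theta = grid[best].astype(float)
    interior = (best > 0) & (best < grid_size - 1)
    bi = best[interior]
    sm = sse_grid[interior, bi - 1]
    s0 = sse_grid[interior, bi]
    sp = sse_grid[interior, bi + 1]
    denom = sm - 2 * s0 + sp
    shift = np.where(denom > 0, 0.5 * h * (sm - sp) / np.where(denom == 0, 1, denom), 0.0)
    theta[interior] = grid[bi] + np.clip(shift, -h, h)

    coef, _ = _solve(_designs(carrier_of(theta)))

    if spec.target == "ER" or spec.classical:
        return coef[:, j]
    # gauge convention: F = sample mean of the linear (P) block; permuting a
    # column leaves its sample mean unchanged, so the block means are fixed
    means = np.array([c.mean() for c in lin_cols])
    f = coef[:, :k_lin] @ means
    if kind == "A":
        return coef[:, j] / f
    return coef[:, j] / f**2


def coefficient_significance(
    records: pd.DataFrame,
    spec: ModelSpec,
    coefficient: str,
    n_shuffles: int = 10_000,
    seed: int | None = None,
    grid_size: int = 41,
) -> NullDistribution:
    """Permutation significance of one regression coefficient.

    Each shuffle permutes the coefficient's driver column across records
    (breaking only the dependent-independent pairing under test), refits the
    model and records the coefficient estimate; the observed estimate is
    tested double-tailed against this null.  The observed estimate runs
    through the same batched profile fit as the null draws.
    """
    rng = np.random.default_rng(seed)
    n = len(records)
    perms = np.empty((n_shuffles + 1, n), dtype=np.intp)
    perms[0] = np.arange(n)  # identity -> observed estimate
    for i in range(n_shuffles):
        perms[i + 1] = rng.permutation(n)
    values = _batched_coefficient_estimates(records, spec, coefficient, perms, grid_size)
    bad = ~np.isfinite(values)
    if bad[0]:
        raise FitError(f"observed fit failed for {spec.describe()}")
    if bad.sum() > 0.10 * n_shuffles:
        raise FitError(f"{int(bad.sum())}/{n_shuffles} shuffled refits failed for {spec.describe()}")
    observed, draws = values[0], values[1:][np.isfinite(values[1:])]
    return NullDistribution(
        observed=float(observed),
        draws=draws,
        n_shuffles=n_shuffles,
        seed=seed,
        p_two_tailed=_pvalue(observed, draws, exhaustive=False),
        statistic=f"coefficient:{coefficient}",
    )


def model_parameter_difference_test(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    spec: ModelSpec,
    parameter: str,
    n_shuffles: int = 10_000,
    seed: int | None = None,
    max_failure_rate: float = 0.10,
) -> NullDistribution:
    """Randomization test for a between-series difference of one fitted
    model parameter.

    The observed statistic is the parameter fitted separately on the two
    series; the null mixes records across series (group sizes preserved),
    refits both models and records the difference.  ``parameter`` may name a
    reported parameter (a1, A1, ...) or an identifiable one (P1 = F*A1,
    rho, ...); for GPP block coefficients the identifiable products are the
    gauge-invariant choice (the reported A_i are normalized block shapes and
    barely move when the whole block scales).
    """

    def _value(fit):
        if parameter in fit.params:
            return fit.params[parameter]
        return fit.ident_params[parameter]

    fa = fit_model(records_a, spec, diagnostics=False)
    fb = fit_model(records_b, spec, diagnostics=False)
    observed = _value(fa) - _value(fb)
    fit_kw = dict(diagnostics=False, check_rank=False, grid_size=21)

    pooled = pd.concat([records_a, records_b], ignore_index=True)
    na = len(records_a)
    rng = np.random.default_rng(seed)
    draws = np.empty(n_shuffles)
    failures = 0
    for i in range(n_shuffles):
        idx = rng.permutation(len(pooled))
        pa = pooled.iloc[idx[:na]]
        pb = pooled.iloc[idx[na:]]
        try:
            draws[i] = _value(fit_model(pa, spec, **fit_kw)) - _value(fit_model(pb, spec, **fit_kw))
        except FitError:
            draws[i] = np.nan
            failures += 1
    if failures > max_failure_rate * n_shuffles:
        raise FitError(f"{failures}/{n_shuffles} shuffled refits failed")
    draws = draws[np.isfinite(draws)]
    return NullDistribution(
        observed=float(observed),
        draws=draws,
        n_shuffles=n_shuffles,
        seed=seed,
        p_two_tailed=_pvalue(observed, draws, exhaustive=False),
        statistic=f"parameter_difference:{parameter}",
    )
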