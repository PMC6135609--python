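"""Per-trace exponential fits and global multi-trace kinetic fitting.

Two analysis layers:

1. *Model-free*: each trace is fitted with a single exponential to extract an
   apparent rate ``kobs``; a linear replot of ``kobs`` against the varied
   concentration estimates the second-order on-rate (slope) and first-order
   off-rate (intercept) under pseudo-first-order conditions.
2. *Global*: a full kinetic scheme is integrated for every trace in a
   concentration series simultaneously and its rate constants optimized
   against all data points at once.  Rate constants are optimized in log10
   space (they span ~5 orders of magnitude), with Latin-hypercube multistart
   around data-driven initial guesses, Jacobian-based standard errors,
   profile-likelihood bounds for weakly identified constants, and a residual
   bootstrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import linregress, qmc

from .models import RateParameters, Scheme, SpeciesState, pre_equilibrate
from .simulate import (
    AnisotropyCalibration,
    Trace,
    TraceSeries,
    simulate_trajectory,
    state_to_anisotropy,
)

__all__ = [
    "ExpFit",
    "LinearReplot",
    "GlobalFitResult",
    "ProfileBound",
    "BootstrapResult",
    "fit_single_exponential",
    "replot_kobs",
    "global_fit",
    "profile_bound",
    "bootstrap_uncertainty",
    "default_free_params",
    "model_trace",
]

#: Optimization bounds on log10 of any rate constant.
LOG_BOUNDS = (-5.0, 4.0)


@dataclass
class ExpFit:
    """Single-exponential fit r(t) = offset + amplitude * exp(-kobs * t)."""

    kobs: float
    amplitude: float
    offset: float
    residuals: np.ndarray
    rmse: float
    converged: bool
    message: str = ""


@dataclass
class LinearReplot:
    """Ordinary least-squares line through (concentration, kobs) pairs."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    r_squared: float
    n: int


@dataclass
class GlobalFitResult:
    params: RateParameters
    free_names: tuple
    param_se: dict
    chi2: float
    n_data: int
    n_free: int
    per_trace_residuals: list
    per_trace_rmse: list
    fitted_values: list
    multistart_log: list
    converged: bool
    seed: int
    scheme: Scheme
    message: str = ""

    def free_values(self) -> dict:
        return {n: getattr(self.params, n) for n in self.free_names}


@dataclass
class ProfileBound:
    """Profile-likelihood bound: the parameter value at which refitting all
    other free parameters raises chi2 by ``chi2_threshold``."""

    name: str
    bound_type: str
    value: float
    chi2_threshold: float
    estimate: float
    chi2_min: float
    unbounded: bool = False


@dataclass
class BootstrapResult:
    intervals: dict
    samples: dict
    n_boot: int
    seed: int
    level: float


def fit_single_exponential(trace: Trace) -> ExpFit:
    """Least-squares single-exponential fit of one trace.

    ``kobs`` is constrained non-negative and initialized from the time to
    half amplitude.  A trace whose excursion is indistinguishable from noise
    (e.g. no observable release at very low competitor) is reported with
    ``converged=False`` and ``kobs = 0`` rather than raising.
    """
    t = np.asarray(trace.times, dtype=float)
    v = np.asarray(trace.values, dtype=float)
    if len(t) < 10:
        raise ValueError(f"need at least 10 points to fit, got {len(t)}")
    span = float(v.max() - v.min())
    if span == 0.0:
        return ExpFit(
            kobs=0.0,
            amplitude=0.0,
            offset=float(v[0]),
            residuals=v - v[0],
            rmse=0.0,
            converged=False,
            message="constant trace: no kinetics to fit",
        )
    # Robust per-point noise estimate from first differences.
    noise = float(np.std(np.diff(v)) / math.sqrt(2.0))

    tail = max(5, len(v) // 20)
    v_inf = float(np.mean(v[-tail:]))
    v_0 = float(np.mean(v[: max(3, len(v) // 50)]))
    amp_raw = v_0 - v_inf
    half = v_inf + amp_raw / 2.0
    crossing = np.nonzero(
        (v - half) * np.sign(amp_raw) <= 0 if amp_raw != 0 else np.ones_like(v, bool)
    )[0]
    t_half = t[crossing[0]] if len(crossing) else t[len(t) // 2]
    dt_half = max(t_half - t[0], (t[-1] - t[0]) / len(t))
    k0 = math.log(2.0) / dt_half
    a0 = amp_raw * math.exp(min(k0 * t[0], 50.0))

    def resid(x):
        offset, amp, kobs = x
        return offset + amp * np.exp(-np.clip(kobs * t, None, 700.0)) - v

    sol = optimize.least_squares(
        resid,
        x0=[v_inf, a0, k0],
        bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
        method="trf",
        x_scale=[max(abs(v_inf), 0.01), max(abs(a0), 0.01), max(k0, 1e-3)],
    )
    offset, amp, kobs = sol.x
    residuals = v - (offset + amp * np.exp(-np.clip(kobs * t, None, 700.0)))
    rmse = float(np.sqrt(np.mean(residuals**2)))
    if abs(amp) < 4.0 * noise:
        return ExpFit(
            kobs=0.0,
            amplitude=float(amp),
            offset=float(np.mean(v)),
            residuals=v - np.mean(v),
            rmse=float(np.std(v)),
            converged=False,
            message=(
                "flat trace: fitted amplitude "
                f"{amp:.2e} is within noise ({noise:.2e}); no observable kinetics"
            ),
        )
    return ExpFit(
        kobs=float(kobs),
        amplitude=float(amp),
        offset=float(offset),
        residuals=residuals,
        rmse=rmse,
        converged=bool(sol.success),
        message=sol.message,
    )


def replot_kobs(series_fits) -> LinearReplot:
    """OLS replot of kobs against the varied concentration.

    Under pseudo-first-order conditions the slope is the apparent
    second-order association rate constant and the intercept the first-order
    dissociation rate constant.
    """
    pairs = [
        (float(c), f.kobs if isinstance(f, ExpFit) else float(f))
        for c, f in series_fits
    ]
    if len(pairs) < 3:
        raise ValueError(f"replot needs >= 3 (concentration, kobs) pairs, got {len(pairs)}")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    res = linregress(x, y)
    return LinearReplot(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_se=float(res.stderr),
        intercept_se=float(res.intercept_stderr),
        r_squared=float(res.rvalue**2),
        n=len(pairs),
    )


def default_free_params(scheme: Scheme | str) -> tuple:
    """Which rate constants a scheme's standard experiment can determine."""
    scheme = Scheme.parse(scheme)
    if scheme is Scheme.ASSOCIATION:
        return ("k1", "k_m1")
    if scheme is Scheme.SIMPLE_COMPETITION:
        return ("k_m1",)
    return ("k2", "k_m2", "k3", "k_m3")


def model_trace(
    scheme: Scheme,
    params: RateParameters,
    trace: Trace,
    cal: AnisotropyCalibration,
) -> np.ndarray:
    """Noise-free model anisotropy for one trace's conditions.

    Association traces start from fully free species; dissociation traces
    start from the protein/probe pre-equilibrium (computed with the current
    ``k1``/``k_m1``) with competitor sites added at t = 0.  Under the ternary
    mechanism the binary complexes do not dissociate directly during the
    exchange phase (probe release goes through the ternary complex only), so
    ``k_m1`` affects only the initial state; mirrors the generator.
    """
    if scheme is Scheme.ASSOCIATION:
        init = SpeciesState(P=trace.total_p, Dstar=trace.total_dstar)
        traj = simulate_trajectory(scheme, params, init, trace.times)
    else:
        init = pre_equilibrate(
            trace.total_p, trace.total_dstar, params.k1, params.k_m1
        ).evolve(D=trace.competitor_sites)
        phase = params.evolve(k_m1=0.0) if scheme is Scheme.TERNARY else params
        traj = simulate_trajectory(scheme, phase, init, trace.times)
    return state_to_anisotropy(traj, cal, trace.total_dstar)


def _assemble(base: RateParameters, free_names, x_log: np.ndarray) -> RateParameters:
    return base.evolve(**{n: 10.0 ** float(xi) for n, xi in zip(free_names, x_log)})


#: Finite-difference step in log10-parameter space.  Must sit well above the
#: relative noise the adaptive ODE integrator leaves in the objective
#: (~rtol); smaller steps produce garbage gradients along sloppy parameter
#: combinations and stall the optimizer.
DIFF_STEP = 1e-3


def _fd_jacobian(fun, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Forward-difference Jacobian of a residual vector function."""
    f0 = fun(x)
    J = np.empty((len(f0), len(x)))
    for i in range(len(x)):
        xp = x.copy()
        xp[i] += h
        J[:, i] = (fun(xp) - f0) / h
    return J


def _series_residuals(series, scheme, params, cal):
    parts = []
    for trace in series.traces:
        model = model_trace(scheme, params, trace, cal)
        parts.append(model - trace.values)
    return parts


def _heuristic_start(series: TraceSeries, scheme: Scheme, free_names):
    """Data-driven initial guesses from per-trace exponential fits.

    Returns the primary guess plus structured alternates.  For the ternary
    scheme the observable mostly constrains ``k3`` and the lumped saturation
    constant K = (k_m2 + k3)/k2 (formation and loss of the ternary complex are
    signal-invisible because both bound species share one anisotropy), leaving
    a sloppy ridge along the k_m2/k2 split; the alternates walk that ridge so
    the multistart covers it explicitly.
    """
    lo, hi = LOG_BOUNDS
    guess = {}
    alternates = []
    fits = []
    for trace in series.traces:
        try:
            f = fit_single_exponential(trace)
        except ValueError:
            continue
        if f.converged and f.kobs > 0:
            fits.append((trace.varied, f.kobs))
    if scheme is Scheme.ASSOCIATION:
        guess = {"k1": 1.0, "k_m1": 1.0}
        if len(fits) >= 3:
            rep = replot_kobs(fits)
            guess["k1"] = max(rep.slope, 10.0**lo)
            guess["k_m1"] = max(rep.intercept, 0.1)
        elif fits:
            c, k = fits[0]
            guess["k1"] = max(k / max(c, 1.0), 10.0**lo)
    elif scheme is Scheme.SIMPLE_COMPETITION:
        kobs = [k for _, k in fits]
        guess = {"k_m1": float(np.median(kobs)) if kobs else 1.0}
    else:
        # Hyperbolic kobs(D) = kmax * D / (D + K): kmax estimates k3 and K the
        # lumped constant (k_m2 + k3)/k2.
        k3_g, K_g = 10.0, 1000.0
        if len(fits) >= 3:
            d = np.array([c for c, _ in fits])
            k = np.array([k for _, k in fits])
            try:
                popt, _ = optimize.curve_fit(
                    lambda x, kmax, K: kmax * x / (x + K),
                    d,
                    k,
                    p0=[1.2 * k.max(), float(np.median(d))],
                    bounds=([1e-5, 1e-2], [1e4, 1e7]),
                    maxfev=2000,
                )
                k3_g, K_g = float(popt[0]), float(popt[1])
            except RuntimeError:
                k3_g = 1.2 * float(k.max())
                K_g = float(np.median(d))
        elif fits:
            k3_g = 1.2 * max(k for _, k in fits)

        def ridge_point(m, r):
            k_m2 = m * k3_g
            k2 = (k_m2 + k3_g) / K_g
            return {"k2": k2, "k_m2": k_m2, "k3": k3_g, "k_m3": r * k2}

        guess = ridge_point(1.0, 1.0 / 3.0)
        for m in (0.3, 3.0, 10.0, 30.0, 100.0):
            for r in (1.0 / 3.0, 1.0 / 30.0):
                alternates.append(ridge_point(m, r))
    clip = lambda v: float(np.clip(v, 10.0**lo, 10.0**hi))
    primary = {n: clip(guess.get(n, 1.0)) for n in free_names}
    alternates = [
        {n: clip(a.get(n, primary[n])) for n in free_names} for a in alternates
    ]
    return primary, alternates


def global_fit(
    series: TraceSeries,
    scheme: Scheme | str,
    *,
    free_params=None,
    fixed_params: RateParameters | None = None,
    n_starts: int = 16,
    seed: int = 0,
    ftol: float = 1e-12,
    xtol: float = 1e-12,
    x0_override: dict | None = None,
) -> GlobalFitResult:
    """Fit a kinetic scheme to all traces of a series simultaneously.

    ``free_params`` names the rate constants to optimize (defaults per
    scheme); everything else is taken from ``fixed_params`` -- in particular
    ``k1``/``k_m1`` stay fixed at association-derived values during ternary
    dissociation fits unless explicitly freed.  Optimization runs in log10
    space from ``n_starts`` starting points: a data-driven heuristic plus a
    seeded Latin hypercube spanning +/- 2 decades around it.  Ties in final
    chi2 (within 1e-10) resolve to the earliest start for determinism.
    """
    scheme = Scheme.parse(scheme)
    free_names = tuple(free_params) if free_params else default_free_params(scheme)
    if not free_names:
        raise ValueError("at least one free parameter is required")
    base = fixed_params if fixed_params is not None else RateParameters()
    if scheme is not Scheme.ASSOCIATION:
        probe = base.evolve(**{n: 1.0 for n in free_names})
        probe.require("k1", "k_m1")
    cal = series.calibration
    n_data = sum(len(tr.times) for tr in series.traces)
    n_free = len(free_names)
    lo, hi = LOG_BOUNDS

    def residuals_at(params):
        try:
            parts = _series_residuals(series, scheme, params, cal)
        except (RuntimeError, ValueError):
            return np.full(n_data, 1e3)
        return np.concatenate(parts)

    def objective(x_log):
        return residuals_at(_assemble(base, free_names, x_log))

    def to_vec(values: dict) -> np.ndarray:
        return np.clip(
            [math.log10(max(values[n], 10.0**lo)) for n in free_names], lo, hi
        )

    if x0_override is not None:
        starts = [to_vec(x0_override)]
    else:
        heur, alternates = _heuristic_start(series, scheme, free_names)
        pool = [to_vec(heur)] + [to_vec(a) for a in alternates]
        if n_starts > 1:
            n_lhs = max(2 * n_starts, 15)
            sampler = qmc.LatinHypercube(d=n_free, seed=seed)
            unit = sampler.random(n=n_lhs)
            spread = pool[0] + (unit * 4.0 - 2.0)  # +/- 2 decades around heuristic
            pool.extend(np.clip(s, lo + 0.01, hi - 0.01) for s in spread)
        # Cheap screening: one objective evaluation per candidate, then local
        # optimization from the n_starts most promising points (the primary
        # heuristic is always kept).
        scores = [float(np.sum(objective(x) ** 2)) for x in pool]
        order = np.argsort(scores, kind="stable")
        picked = [0] + [int(i) for i in order if i != 0]
        starts = [pool[i] for i in picked[:n_starts]]

    def local_optimize(x0):
        """TRF with a few restarts: re-running from the endpoint resets the
        trust region and lets the search traverse long sloppy valleys."""
        x, sol_best, chi2_best = x0, None, math.inf
        for _ in range(4):
            sol = optimize.least_squares(
                objective,
                x0=x,
                bounds=(lo, hi),
                method="trf",
                x_scale="jac",
                diff_step=DIFF_STEP,
                ftol=ftol,
                xtol=xtol,
                gtol=1e-14,
            )
            chi2 = float(np.sum(sol.fun**2))
            if chi2 < chi2_best - 1e-12:
                improved = chi2_best - chi2
                sol_best, chi2_best, x = sol, chi2, sol.x
                if improved < 1e-6 * max(chi2_best, 1e-30):
                    break
            else:
                break
        return sol_best, chi2_best

    best = None
    log = []
    for idx, x0i in enumerate(starts):
        start_values = dict(zip(free_names, 10.0 ** np.asarray(x0i)))
        try:
            sol, chi2 = local_optimize(np.clip(x0i, lo, hi))
            ok = bool(sol.success)
        except Exception as exc:  # keep per-start diagnostics, never die
            log.append({"start": start_values, "chi2": math.inf,
                        "success": False, "error": str(exc)})
            continue
        log.append({"start": start_values, "chi2": chi2, "success": ok})
        if best is None or chi2 < best[0] - 1e-10:
            best = (chi2, idx, sol)

    if best is None:
        return GlobalFitResult(
            params=base,
            free_names=free_names,
            param_se={},
            chi2=math.inf,
            n_data=n_data,
            n_free=n_free,
            per_trace_residuals=[],
            per_trace_rmse=[],
            fitted_values=[],
            multistart_log=log,
            converged=False,
            seed=seed,
            scheme=scheme,
            message="all multistart optimizations failed",
        )

    chi2, _, sol = best
    values = {n: 10.0 ** float(xi) for n, xi in zip(free_names, sol.x)}
    params = base.evolve(**values)
    fitted = [model_trace(scheme, params, tr, cal) for tr in series.traces]
    residuals = [tr.values - f for tr, f in zip(series.traces, fitted)]
    rmse = [float(np.sqrt(np.mean(r**2))) for r in residuals]

    # Standard errors from a finite-difference Jacobian in plain log10-rate
    # coordinates at the optimum: se(k) = k * ln(10) * se(log10 k).
    param_se = {name: 0.0 for name in free_names}
    dof = n_data - n_free
    if dof > 0 and chi2 > 0:
        x_direct = np.array(
            [math.log10(max(values[n], 10.0**lo)) for n in free_names]
        )
        J = _fd_jacobian(
            lambda x: residuals_at(_assemble(base, free_names, x)), x_direct
        )
        jtj = J.T @ J
        try:
            cov_log = np.linalg.inv(jtj) * (chi2 / dof)
        except np.linalg.LinAlgError:
            cov_log = np.linalg.pinv(jtj) * (chi2 / dof)
        se_log = np.sqrt(np.clip(np.diag(cov_log), 0.0, None))
        for name, xi, si in zip(free_names, x_direct, se_log):
            param_se[name] = float(10.0**xi * math.log(10.0) * si)

    return GlobalFitResult(
        params=params,
        free_names=free_names,
        param_se=param_se,
        chi2=chi2,
        n_data=n_data,
        n_free=n_free,
        per_trace_residuals=residuals,
        per_trace_rmse=rmse,
        fitted_values=fitted,
        multistart_log=log,
        converged=bool(sol.success),
        seed=seed,
        scheme=scheme,
        message=sol.message,
    )


def profile_bound(
    series: TraceSeries,
    scheme: Scheme | str,
    param_name: str,
    *,
    delta_chi2: float = 3.84,
    bound_type: str = "upper",
    free_params=None,
    fixed_params: RateParameters | None = None,
    n_starts: int = 4,
    seed: int = 0,
    max_decades: float = 3.0,
    step_decades: float = 0.15,
    fit: GlobalFitResult | None = None,
) -> ProfileBound:
    """Profile-likelihood bound on one rate constant.

    Scans ``param_name`` away from its point estimate on a log grid, refitting
    all other free parameters at each value (warm-started at the previous
    optimum), until the variance-normalized chi2 rises by ``delta_chi2``
    (default 3.84: 95% for one parameter); the residual variance is estimated
    from the fit itself as chi2_min/dof, so the raw threshold is
    chi2_min * (1 + delta_chi2/dof).  The crossing is located by linear
    interpolation.  If chi2 never crosses within ``max_decades`` the bound is
    reported unbounded.
    """
    scheme = Scheme.parse(scheme)
    free_names = tuple(free_params) if free_params else default_free_params(scheme)
    if param_name not in free_names:
        raise ValueError(f"{param_name!r} is not among the free parameters {free_names}")
    if bound_type not in ("upper", "lower"):
        raise ValueError("bound_type must be 'upper' or 'lower'")
    if fit is None:
        fit = global_fit(
            series, scheme, free_params=free_names,
            fixed_params=fixed_params, n_starts=n_starts, seed=seed,
        )
    if not fit.converged:
        raise RuntimeError("profile bound requires a converged global fit")
    estimate = getattr(fit.params, param_name)
    if delta_chi2 == 0.0:
        return ProfileBound(param_name, bound_type, float(estimate), 0.0,
                            float(estimate), fit.chi2)
    dof = max(fit.n_data - fit.n_free, 1)
    sigma2 = fit.chi2 / dof
    threshold = fit.chi2 + delta_chi2 * sigma2
    others = tuple(n for n in free_names if n != param_name)
    base = fixed_params if fixed_params is not None else RateParameters()
    sign = 1.0 if bound_type == "upper" else -1.0
    # A near-zero estimate has no usable log anchor; scan from a small floor.
    anchor = max(float(estimate), 10.0 ** LOG_BOUNDS[0] * 10.0)
    log_anchor = math.log10(anchor)

    warm = {n: getattr(fit.params, n) for n in others}
    prev = (log_anchor, fit.chi2)
    n_steps = int(math.ceil(max_decades / step_decades))
    for i in range(1, n_steps + 1):
        lv = log_anchor + sign * i * step_decades
        fixed_i = base.evolve(**{param_name: 10.0**lv})
        if others:
            sub = global_fit(
                series, scheme, free_params=others, fixed_params=fixed_i,
                n_starts=1, seed=seed, x0_override=warm,
            )
            chi2_i = sub.chi2
            warm = {n: getattr(sub.params, n) for n in others}
        else:
            cal = series.calibration
            parts = _series_residuals(series, scheme, fixed_i, cal)
            chi2_i = float(sum(np.sum(p**2) for p in parts))
        if chi2_i >= threshold:
            lv_prev, chi2_prev = prev
            frac = (threshold - chi2_prev) / (chi2_i - chi2_prev)
            lv_cross = lv_prev + frac * (lv - lv_prev)
            return ProfileBound(param_name, bound_type, float(10.0**lv_cross),
                                delta_chi2, float(estimate), fit.chi2)
        prev = (lv, chi2_i)
    return ProfileBound(param_name, bound_type,
                        math.inf if sign > 0 else 0.0,
                        delta_chi2, float(estimate), fit.chi2, unbounded=True)


def bootstrap_uncertainty(
    series: TraceSeries,
    scheme: Scheme | str,
    *,
    n_boot: int = 200,
    seed: int = 0,
    level: float = 0.95,
    free_params=None,
    fixed_params: RateParameters | None = None,
    fit: GlobalFitResult | None = None,
) -> BootstrapResult:
    """Residual-resampling bootstrap percentile intervals per free parameter.

    Residuals are resampled with replacement within each trace, added back to
    the fitted model, and the fit repeated from the point estimate.
    Deterministic under a fixed seed.
    """
    if n_boot < 10:
        raise ValueError(f"n_boot must be >= 10, got {n_boot}")
    scheme = Scheme.parse(scheme)
    free_names = tuple(free_params) if free_params else default_free_params(scheme)
    if fit is None:
        fit = global_fit(series, scheme, free_params=free_names,
                         fixed_params=fixed_params, seed=seed)
    if not fit.converged:
        raise RuntimeError("bootstrap requires a converged global fit")
    rng = np.random.default_rng(seed)
    point = {n: max(getattr(fit.params, n), 10.0 ** LOG_BOUNDS[0]) for n in free_names}
    samples = {n: [] for n in free_names}
    for _ in range(n_boot):
        boot_traces = []
        for trace, model, resid in zip(
            series.traces, fit.fitted_values, fit.per_trace_residuals
        ):
            idx = rng.integers(0, len(resid), len(resid))
            boot_traces.append(
                Trace(times=trace.times, values=model + resid[idx], meta=trace.meta)
            )
        boot_series = TraceSeries(
            traces=boot_traces, scheme=series.scheme,
            calibration=series.calibration, instrument=series.instrument,
            meta=series.meta,
        )
        bfit = global_fit(
            boot_series, scheme, free_params=free_names,
            fixed_params=fixed_params, n_starts=1, seed=seed,
            x0_override=point,
        )
        for n in free_names:
            samples[n].append(getattr(bfit.params, n))
    alpha = (1.0 - level) / 2.0
    intervals = {
        n: (
            float(np.quantile(samples[n], alpha)),
            float(np.quantile(samples[n], 1.0 - alpha)),
        )
        for n in free_names
    }
    return BootstrapResult(
        intervals=intervals,
        samples={n: np.array(v) for n, v in samples.items()},
        n_boot=n_boot,
        seed=seed,
        level=level,
    )
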