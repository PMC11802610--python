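"""Simulation, noisy-data generation and bootstrap parameter estimation.

This module turns a model specification into numerical experiments: simulate
trajectories on a time grid, add Gaussian measurement noise realization by
realization, then refit the unknown quantities to every realization with
multistart local nonlinear least squares.  The spread of the resulting
estimate distributions quantifies practical identifiability.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Mapping, Sequence

import numpy as np
import sympy as sp
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .model_io import GENERIC, ModelError, ModelSpec, input_deriv_order

__all__ = [
    "Polynomial",
    "PiecewiseConstant",
    "SimDataset",
    "BootstrapResult",
    "simulate",
    "add_noise",
    "bootstrap_fit",
    "theta1_from_derivatives",
]


class Polynomial:
    """Polynomial input signal ``c0 + c1*t + c2*t**2 + ...``."""

    def __init__(self, coeffs: Sequence[float]):
        self.coeffs = [float(c) for c in coeffs] or [0.0]

    @property
    def max_nonzero_deriv(self) -> int:
        deg = 0
        for i, c in enumerate(self.coeffs):
            if c != 0.0:
                deg = i
        return deg

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for c in reversed(self.coeffs):
            out = out * t + c
        return out

    def breakpoints(self, t0: float, tf: float) -> list[float]:
        return []


class PiecewiseConstant:
    """Piecewise-constant input: ``values[i]`` on ``[breaks[i-1], breaks[i])``.

    ``len(values) == len(breaks) + 1``; the signal is right-continuous.
    """

    max_nonzero_deriv = 0  # constant within each segment

    def __init__(self, breaks: Sequence[float], values: Sequence[float]):
        self.breaks = [float(b) for b in breaks]
        self.values = [float(v) for v in values]
        if sorted(self.breaks) != self.breaks:
            raise ValueError("breakpoints must be increasing")
        if len(self.values) != len(self.breaks) + 1:
            raise ValueError("need len(values) == len(breaks) + 1")

    def __call__(self, t):
        idx = np.searchsorted(self.breaks, np.asarray(t, dtype=float), side="right")
        return np.asarray(self.values, dtype=float)[idx]

    def breakpoints(self, t0: float, tf: float) -> list[float]:
        return [b for b in self.breaks if t0 < b < tf]


@dataclasses.dataclass
class SimDataset:
    """One experiment: a time grid with clean and noisy output trajectories."""

    time_grid: np.ndarray
    clean: np.ndarray  # (n_t, n_y)
    noisy: list[np.ndarray] = dataclasses.field(default_factory=list)
    sigma: float = 0.0
    seed: int | None = None
    input_trace: np.ndarray | None = None  # (n_t, n_u)
    values: dict[str, float] = dataclasses.field(default_factory=dict)
    inputs: dict[str, Callable] = dataclasses.field(default_factory=dict)

    @property
    def n_realizations(self) -> int:
        return len(self.noisy)

    def to_csv(self, experiment_id: int = 0, realization: int | None = None) -> str:
        """Dataset as CSV text (columns: time, output_1.., experiment_id)."""
        y = self.clean if realization is None else self.noisy[realization]
        n_y = y.shape[1]
        header = "time," + ",".join(f"output_{j + 1}" for j in range(n_y))
        lines = [header + ",experiment_id"]
        for i, t in enumerate(self.time_grid):
            vals = ",".join(repr(float(v)) for v in y[i])
            lines.append(f"{float(t)!r},{vals},{experiment_id}")
        return "\n".join(lines) + "\n"


class _CompiledModel:
    """Model compiled to fast numeric callables f(x, u, p) and g(x, u, p)."""

    def __init__(self, model: ModelSpec):
        model.validate()
        const = dict(model.constants)
        dyn = [sp.sympify(e).xreplace(const) for e in model.dynamics]
        outs = [sp.sympify(e).xreplace(const) for e in model.outputs]
        for expr in dyn + outs:
            for s in expr.free_symbols:
                for spec in model.inputs:
                    if (input_deriv_order(s, spec.name) or 0) > 0:
                        raise ModelError(
                            f"cannot simulate: equations contain input derivative {s}"
                        )
        self.model = model
        self.states = list(model.states)
        self.params = list(model.params_unknown)
        self.input_names = [spec.name for spec in model.inputs]
        args = self.states + [sp.Symbol(n) for n in self.input_names] + self.params
        self._f = sp.lambdify(args, dyn, modules="numpy")
        self._g = sp.lambdify(args, outs, modules="numpy")
        self.n_y = model.n_y

    def rhs(self, input_fns: Sequence[Callable], pvals: Sequence[float]) -> Callable:
        f = self._f

        def fun(t, x):
            u = [fn(t) for fn in input_fns]
            return f(*x, *u, *pvals)

        return fun

    def outputs_at(
        self,
        t_grid: np.ndarray,
        x: np.ndarray,
        input_fns: Sequence[Callable],
        pvals: Sequence[float],
    ) -> np.ndarray:
        n_t = len(t_grid)
        y = np.empty((n_t, self.n_y))
        u_cols = [fn(t_grid) for fn in input_fns]
        for i in range(n_t):
            u = [float(col[i]) if np.ndim(col) else float(col) for col in u_cols]
            y[i] = self._g(*x[i], *u, *pvals)
        return y


def _integrate(
    compiled: _CompiledModel,
    x0: Sequence[float],
    pvals: Sequence[float],
    input_fns: Sequence[Callable],
    t_grid: np.ndarray,
    rtol: float,
    atol: float,
) -> np.ndarray:
    """Integrate segment-by-segment so piecewise-constant breakpoints are exact."""
    t0, tf = float(t_grid[0]), float(t_grid[-1])
    breaks = sorted({b for fn in input_fns for b in fn.breakpoints(t0, tf)})
    edges = [t0] + breaks + [tf]
    fun = compiled.rhs(input_fns, pvals)
    x = np.empty((len(t_grid), len(x0)))
    xi = np.asarray(x0, dtype=float)
    filled = 0
    for a, b in zip(edges[:-1], edges[1:]):
        # evaluate the input just inside the segment (right-continuous signal)
        mask = (t_grid >= a - 1e-12) & (t_grid <= b + 1e-12) & (
            np.arange(len(t_grid)) >= filled
        )
        t_eval = t_grid[mask]
        if b > a:
            sol = solve_ivp(
                fun,
                (a, b),
                xi,
                method="LSODA",
                t_eval=t_eval if len(t_eval) else None,
                rtol=rtol,
                atol=atol,
                dense_output=not len(t_eval),
            )
            if not sol.success:
                raise ModelError(
                    f"integration failed at t={sol.t[-1] if len(sol.t) else a:g}: "
                    f"{sol.message}"
                )
            if len(t_eval):
                x[filled : filled + len(t_eval)] = sol.y.T
                filled += len(t_eval)
            xi = sol.y[:, -1] if sol.y.size else xi
        elif len(t_eval):
            x[filled : filled + len(t_eval)] = xi
            filled += len(t_eval)
    if filled != len(t_grid):  # pragma: no cover - grid/segment bookkeeping guard
        raise ModelError("time grid points left uncovered by integration segments")
    return x


def simulate(
    model: ModelSpec,
    values: Mapping[str, float],
    inputs: Mapping[str, Callable] | None = None,
    t_grid: Sequence[float] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> SimDataset:
    """Noiseless simulation of ``model`` on ``t_grid``.

    ``values`` assigns every unknown parameter and every initial state (by
    state name).  ``inputs`` maps input names to callables of time
    (:class:`Polynomial`, :class:`PiecewiseConstant`, or any callable with an
    optional ``breakpoints`` method).  Piecewise-constant inputs are
    integrated segment by segment so the breakpoints are hit exactly.
    """
    compiled = _CompiledModel(model)
    if t_grid is None:
        raise ValueError("t_grid is required")
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing with >= 2 points")

    missing = [
        s.name
        for s in list(model.states) + list(model.params_unknown)
        if s.name not in values
    ]
    if missing:
        raise ModelError(f"values missing for: {', '.join(missing)}")
    inputs = dict(inputs or {})
    for spec in model.inputs:
        if spec.name not in inputs:
            if spec.fixed_function is not None:
                inputs[spec.name] = spec.fixed_function
            else:
                raise ModelError(f"no input function given for input {spec.name!r}")

    input_fns = [_as_input_fn(inputs[n]) for n in compiled.input_names]
    x0 = [float(values[s.name]) for s in compiled.states]
    pvals = [float(values[p.name]) for p in compiled.params]
    x = _integrate(compiled, x0, pvals, input_fns, t_grid, rtol, atol)
    y = compiled.outputs_at(t_grid, x, input_fns, pvals)
    trace = (
        np.column_stack([fn(t_grid) for fn in input_fns]) if input_fns else None
    )
    return SimDataset(
        time_grid=t_grid,
        clean=y,
        sigma=0.0,
        input_trace=trace,
        values={k: float(v) for k, v in values.items()},
        inputs=dict(inputs),
    )


def _as_input_fn(fn: Callable) -> Callable:
    if not callable(fn):
        raise ModelError(f"input function {fn!r} is not callable")
    if not hasattr(fn, "breakpoints"):
        wrapped = lambda t, _fn=fn: _fn(t)  # noqa: E731
        wrapped.breakpoints = lambda t0, tf: []
        return wrapped
    return fn


def add_noise(
    data: SimDataset, sigma: float, n_realizations: int, seed: int
) -> SimDataset:
    """Return a copy of ``data`` with i.i.d. Gaussian noise realizations.

    Perturbations are independent per time point, output and realization;
    identical seeds give identical realizations.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=(n_realizations, *data.clean.shape))
    noisy = [data.clean + noise[r] for r in range(n_realizations)]
    return dataclasses.replace(data, noisy=noisy, sigma=float(sigma), seed=seed)


@dataclasses.dataclass
class BootstrapResult:
    """Estimate distributions from refitting every noise realization."""

    per_quantity: dict[str, np.ndarray]
    nominals: dict[str, float]
    fit_costs: list[float]
    n_failed: int
    seed: int

    def summary(self, name: str) -> dict[str, float]:
        est = np.asarray(self.per_quantity[name])
        lo, hi = np.percentile(est, [2.5, 97.5])
        return {
            "mean": float(np.mean(est)),
            "median": float(np.median(est)),
            "sd": float(np.std(est, ddof=1)) if len(est) > 1 else 0.0,
            "ci_low": float(lo),
            "ci_high": float(hi),
        }

    def cv(self, name: str) -> float:
        """Coefficient of variation |sd / mean| of an estimate distribution."""
        s = self.summary(name)
        return abs(s["sd"] / s["mean"]) if s["mean"] != 0 else math.inf

    def summaries(self) -> dict[str, dict[str, float]]:
        return {name: self.summary(name) for name in self.per_quantity}

    def to_dict(self) -> dict:
        return {
            "estimates": {k: [float(v) for v in a] for k, a in self.per_quantity.items()},
            "summaries": self.summaries(),
            "nominals": self.nominals,
            "fit_costs": self.fit_costs,
            "n_failed": self.n_failed,
            "seed": self.seed,
        }


def _decision_labels(
    model: ModelSpec, unknowns: Sequence[str], n_exp: int
) -> list[tuple[str, str, int | None]]:
    """(label, symbol name, experiment index or None for shared parameters)."""
    param_names = {p.name for p in model.params_unknown}
    state_names = {s.name for s in model.states}
    labels: list[tuple[str, str, int | None]] = []
    for u in unknowns:
        if u in param_names:
            labels.append((u, u, None))
        elif u in state_names:
            for e in range(n_exp):
                label = u if n_exp == 1 else f"{u}[{e}]"
                labels.append((label, u, e))
        else:
            raise ModelError(
                f"unknown quantity {u!r}: not a parameter or state of {model.name}"
            )
    return labels


def bootstrap_fit(
    model: ModelSpec,
    data: SimDataset | Sequence[SimDataset],
    unknowns: Sequence[str],
    bounds: Mapping[str, tuple[float, float]],
    *,
    seed: int = 0,
    n_starts: int = 10,
    log_scale: bool = True,
    rtol: float = 1e-7,
    atol: float = 1e-9,
    max_nfev: int | None = None,
    n_polish: int = 4,
) -> BootstrapResult:
    """Refit ``unknowns`` to every noise realization of ``data``.

    ``data`` is one dataset or one per experiment (realization ``r`` pools
    residuals across experiments; all datasets must hold the same number of
    realizations).  Unknown parameters are shared across experiments; unknown
    initial conditions are estimated per experiment.  Each fit is a
    multistart of local least squares runs, by default in log-transformed
    coordinates (all bounds must then be positive).  Realizations for which
    every start fails are excluded and counted in ``n_failed``.
    """
    datasets = [data] if isinstance(data, SimDataset) else list(data)
    if not datasets or not datasets[0].n_realizations:
        raise ValueError("data must carry at least one noise realization")
    n_real = datasets[0].n_realizations
    if any(d.n_realizations != n_real for d in datasets):
        raise ValueError("all experiments must have the same number of realizations")

    compiled = _CompiledModel(model)
    labels = _decision_labels(model, unknowns, len(datasets))
    if not labels:
        raise ValueError("no unknowns to fit")
    for label, sym, _exp in labels:
        if sym not in bounds:
            raise ModelError(f"no bounds given for unknown {sym!r}")
        lo, hi = bounds[sym]
        if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
            raise ModelError(f"bounds for {sym!r} must be finite with lo < hi")
        if log_scale and lo <= 0:
            raise ModelError(
                f"log-scale fitting needs positive bounds; got {lo} for {sym!r}"
            )

    lo = np.array([bounds[sym][0] for _, sym, _e in labels])
    hi = np.array([bounds[sym][1] for _, sym, _e in labels])
    if log_scale:
        tlo, thi = np.log(lo), np.log(hi)
        decode = np.exp
    else:
        tlo, thi = lo, hi
        decode = lambda v: v  # noqa: E731

    input_fns = [
        [_as_input_fn(d.inputs[n]) for n in compiled.input_names] for d in datasets
    ]
    n_res = sum(d.clean.size for d in datasets)

    def residuals(tvec: np.ndarray, observed: list[np.ndarray]) -> np.ndarray:
        vec = decode(tvec)
        out = []
        for e, d in enumerate(datasets):
            vals = dict(d.values)
            for (label, sym, exp), v in zip(labels, vec):
                if exp is None or exp == e:
                    vals[sym] = float(v)
            try:
                x0 = [vals[s.name] for s in compiled.states]
                pv = [vals[p.name] for p in compiled.params]
                x = _integrate(
                    compiled, x0, pv, input_fns[e], d.time_grid, rtol, atol
                )
                y = compiled.outputs_at(d.time_grid, x, input_fns[e], pv)
            except (ModelError, FloatingPointError, ValueError):
                return np.full(n_res, 1e6)
            out.append((y - observed[e]).ravel())
        res = np.concatenate(out)
        return np.where(np.isfinite(res), res, 1e6)

    rng = np.random.default_rng(seed)
    mid = 0.5 * (tlo + thi)
    estimates: dict[str, list[float]] = {label: [] for label, _s, _e in labels}
    fit_costs: list[float] = []
    n_failed = 0

    for r in range(n_real):
        observed = [d.noisy[r] for d in datasets]
        best_cost, best_vec = math.inf, None
        for s in range(max(n_starts, 1)):
            t0 = mid if s == 0 else rng.uniform(tlo, thi)
            try:
                # chained restarts: sloppy valleys make trf terminate early on
                # xtol, so re-solving from the last point keeps descending
                cost = math.inf
                for _ in range(max(n_polish, 0) + 1):
                    sol = least_squares(
                        residuals,
                        t0,
                        args=(observed,),
                        bounds=(tlo, thi),
                        method="trf",
                        x_scale="jac",
                        max_nfev=max_nfev,
                    )
                    t0 = sol.x
                    if not sol.cost < cost * (1.0 - 1e-10):
                        break
                    cost = sol.cost
            except Exception:
                continue
            if sol.cost < best_cost and np.all(np.isfinite(sol.x)):
                best_cost, best_vec = float(sol.cost), decode(sol.x)
        if best_vec is None or not math.isfinite(best_cost) or best_cost >= 1e9:
            n_failed += 1
            continue
        for (label, _sym, _exp), v in zip(labels, best_vec):
            estimates[label].append(float(v))
        fit_costs.append(best_cost)

    nominals: dict[str, float] = {}
    for label, sym, exp in labels:
        src = datasets[exp if exp is not None else 0]
        nominals[label] = float(src.values.get(sym, math.nan))
    return BootstrapResult(
        per_quantity={k: np.asarray(v) for k, v in estimates.items()},
        nominals=nominals,
        fit_costs=fit_costs,
        n_failed=n_failed,
        seed=seed,
    )


def theta1_from_derivatives(ddy: float, d4y: float, sign: int = +1) -> float:
    """Rate recovered from the second and fourth output derivatives.

    Returns ``sign * sqrt(-d4y / ddy)`` (positive root by default); raises
    for a zero denominator or a negative radicand.
    """
    if ddy == 0:
        raise ValueError("second derivative must be nonzero")
    radicand = -d4y / ddy
    if radicand < 0:
        raise ValueError(f"negative radicand {radicand}")
    if sign not in (+1, -1):
        raise ValueError("sign must be +1 or -1")
    return sign * math.sqrt(radicand)
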