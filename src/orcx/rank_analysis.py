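"""Rank evaluation, variable classification, and derivative escalation.

Ranks at a generic point are computed numerically-exactly: every free symbol
in the matrix is replaced by an independent random rational drawn from a
large range, and the rank of the resulting exact rational matrix is taken
(maximum over a few trials).  Rank degeneration happens only on a
measure-zero algebraic set, so a random point gives the generic rank with
probability one while staying tractable where symbolic rank is not.
"""

from __future__ import annotations

import dataclasses
import json
import random
from typing import Mapping, Sequence

import sympy as sp

from .lie_engine import (
    AugmentedSystem,
    ObsMatrix,
    augment,
    build_obs_matrix,
    min_derivatives,
    replicate_for_experiments,
)
from .model_io import ExperimentSet, ModelError, ModelSpec

__all__ = [
    "SLI",
    "SU",
    "INCONCLUSIVE",
    "CAVEAT_SPECIALIZED",
    "RankReport",
    "generic_rank",
    "classify_variables",
    "analyze",
    "analyze_specialized",
    "v_identifiability",
]

#: Verdict labels.  States read them as observable/unobservable, parameters
#: as identifiable/unidentifiable.
SLI = "SLI/observable"
SU = "SU/unobservable"
INCONCLUSIVE = "inconclusive"

CAVEAT_SPECIALIZED = "sufficient-only: specialized initial condition"
CAVEAT_CAPPED = "relative to capped output derivatives"
CAVEAT_STALLED = "rank saturated below full: model not fully observable/identifiable"

DEFAULT_TRIALS = 3


@dataclasses.dataclass
class RankReport:
    """Outcome of a rank test with per-variable classification."""

    rank: int
    n_xt: int
    full_rank: bool
    n_derivs_used: list[int]
    per_variable: dict[str, str]
    caveats: list[str]
    seed: int
    specialization: dict[str, float] = dataclasses.field(default_factory=dict)

    def variables(self, verdict: str) -> list[str]:
        return [v for v, s in self.per_variable.items() if s == verdict]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _entries(O: ObsMatrix | sp.Matrix) -> sp.Matrix:
    return O.entries if isinstance(O, ObsMatrix) else sp.Matrix(O)


def _random_rational(rng: random.Random) -> sp.Rational:
    # positive rationals from a wide range; a polynomial vanishing on an open
    # subset of the positive orthant vanishes identically, so positivity does
    # not bias the generic rank and keeps fractional powers real-valued.
    return sp.Rational(rng.randint(1, 10**6), rng.randint(1, 10**3))


def sample_numeric(
    M: sp.Matrix, seed: int, trials: int = DEFAULT_TRIALS
) -> list[sp.Matrix]:
    """Exact rational specializations of ``M`` at random generic points."""
    syms = sorted(M.free_symbols, key=lambda s: s.name)
    rng = random.Random(seed)
    out: list[sp.Matrix] = []
    for _ in range(max(trials, 1)):
        for _attempt in range(50):
            sub = {s: _random_rational(rng) for s in syms}
            N = M.xreplace(sub)
            if not any(e.has(sp.zoo, sp.nan, sp.oo, -sp.oo) for e in N):
                out.append(N)
                break
        else:  # pragma: no cover - would need a matrix singular everywhere
            raise ModelError("could not find a finite generic evaluation point")
    return out


def generic_rank(
    O: ObsMatrix | sp.Matrix, seed: int = 0, trials: int = DEFAULT_TRIALS
) -> int:
    """Rank of ``O`` at a generic point (max over random exact evaluations)."""
    M = _entries(O)
    if M.rows == 0 or M.cols == 0:
        return 0
    return max(N.rank() for N in sample_numeric(M, seed, trials))


def _classify_from_samples(
    samples: list[sp.Matrix],
    col_labels: Sequence[str],
    rank: int,
    unresolved_verdict: str,
) -> dict[str, str]:
    per_variable: dict[str, str] = {}
    ncols = len(col_labels)
    if rank == ncols:
        return {name: SLI for name in col_labels}
    for i, name in enumerate(col_labels):
        deleted = max(
            N[:, [j for j in range(ncols) if j != i]].rank() for N in samples
        )
        per_variable[name] = SLI if deleted < rank else unresolved_verdict
    return per_variable


def classify_variables(
    O: ObsMatrix,
    seed: int = 0,
    trials: int = DEFAULT_TRIALS,
    mode: str = "generic",
) -> RankReport:
    """Column-deletion classification of every augmented variable.

    Variable ``i`` is observable/SLI iff deleting column ``i`` decreases the
    rank.  In ``"generic"`` mode an unresolved variable is SU; in
    ``"specialized"`` mode the test is only sufficient, so unresolved
    variables are reported inconclusive.
    """
    if mode not in ("generic", "specialized"):
        raise ValueError(f"unknown mode {mode!r}")
    samples = sample_numeric(O.entries, seed, trials)
    rank = max(N.rank() for N in samples) if O.entries.rows else 0
    n_xt = O.entries.cols
    unresolved = SU if mode == "generic" else INCONCLUSIVE
    per_variable = _classify_from_samples(samples, O.col_labels, rank, unresolved)
    caveats = [] if mode == "generic" else [CAVEAT_SPECIALIZED]
    return RankReport(
        rank=rank,
        n_xt=n_xt,
        full_rank=rank == n_xt,
        n_derivs_used=list(O.derivs_used),
        per_variable=per_variable,
        caveats=caveats,
        seed=seed,
    )


def _prepare_system(
    model: ModelSpec,
    exps: ExperimentSet | None,
    input_bounds: Mapping[str, int | str] | None,
) -> tuple[AugmentedSystem, int]:
    if input_bounds:
        model = dataclasses.replace(
            model,
            inputs=[
                dataclasses.replace(
                    s, max_nonzero_deriv=input_bounds.get(s.name, s.max_nonzero_deriv)
                )
                for s in model.inputs
            ],
        )
    system = augment(model)
    n_e = exps.n_e if exps is not None else 1
    if exps is not None:
        system = replicate_for_experiments(system, exps)
    return system, n_e


def analyze(
    model: ModelSpec,
    exps: ExperimentSet | None = None,
    *,
    seed: int = 0,
    trials: int = DEFAULT_TRIALS,
    input_bounds: Mapping[str, int | str] | None = None,
    max_rounds: int | None = None,
) -> RankReport:
    """Step-wise generic rank analysis with derivative escalation.

    Builds the matrix with the minimum viable derivative count, then adds one
    derivative per output per round until the rank is full or stalls (for a
    generic analysis, rank saturation after a full extra round is
    conclusive).  Returns the classification of every augmented variable.
    """
    system, n_e = _prepare_system(model, exps, input_bounds)
    k = min_derivatives(model.n_x, model.n_theta, model.n_y, n_e)
    if max_rounds is None:
        max_rounds = 2 * system.n_xt + 2
    prev_rank = -1
    O = build_obs_matrix(system, k)
    rank = generic_rank(O, seed, trials)
    rounds = 0
    while rank < system.n_xt and rank > prev_rank and rounds < max_rounds:
        prev_rank = rank
        k += 1
        rounds += 1
        O = build_obs_matrix(system, k)
        rank = generic_rank(O, seed, trials)
    report = classify_variables(O, seed, trials, mode="generic")
    if not report.full_rank:
        report.caveats.append(CAVEAT_STALLED)
    return report


def _specialization_subs(
    model: ModelSpec, point: Mapping[str, float], allow_params: bool = True
) -> dict[sp.Symbol, sp.Expr]:
    declared = {s.name: s for s in model.states}
    if allow_params:
        declared.update({s.name: s for s in model.params_unknown})
    subs: dict[sp.Symbol, sp.Expr] = {}
    for name, value in point.items():
        if name not in declared:
            raise ModelError(
                f"cannot specialize undeclared symbol {name!r}"
                " (states" + (" and parameters" if allow_params else "") + " only)"
            )
        subs[declared[name]] = sp.nsimplify(value, rational=True)
    return subs


def analyze_specialized(
    model: ModelSpec,
    point: Mapping[str, float],
    extra_derivs_max: int | None = None,
    *,
    seed: int = 0,
    trials: int = DEFAULT_TRIALS,
    input_bounds: Mapping[str, int | str] | None = None,
) -> RankReport:
    """Rank test at a specific (non-generic) state/parameter point.

    The matrix rows are specialized at ``point`` as they are built and the
    derivative count escalates up to ``n_d + extra_derivs_max``.  Because no
    stop criterion exists at a specialized point, a full-rank result proves
    SLI/observability but a deficient one proves nothing: unresolved
    variables are reported inconclusive and the report always carries the
    "sufficient-only" caveat.  The default budget is ``2*(n_xt - 1) - n_d``.
    """
    system, _ = _prepare_system(model, None, input_bounds)
    subs = _specialization_subs(model, point)
    nd = min_derivatives(model.n_x, model.n_theta, model.n_y, 1)
    if extra_derivs_max is None:
        extra_derivs_max = max(2 * (system.n_xt - 1) - nd, 0)
    if extra_derivs_max < 0:
        raise ValueError("extra_derivs_max must be >= 0")

    best: ObsMatrix | None = None
    for k in range(nd, nd + extra_derivs_max + 1):
        O = build_obs_matrix(system, k).specialized(subs)
        rank = generic_rank(O, seed, trials)
        best = O
        if rank == system.n_xt:
            break
    report = classify_variables(best, seed, trials, mode="specialized")
    report.specialization = {name: float(v) for name, v in point.items()}
    return report


def v_identifiability(
    model: ModelSpec,
    caps: Sequence[int] | int,
    *,
    exps: ExperimentSet | None = None,
    seed: int = 0,
    trials: int = DEFAULT_TRIALS,
    input_bounds: Mapping[str, int | str] | None = None,
) -> RankReport:
    """Rank test assuming only ``caps[i]`` derivatives of output ``i`` exist.

    Rank and classification are relative to the capped matrix: a variable
    whose column deletion leaves the capped rank unchanged is unidentifiable
    under the caps (it may become identifiable with more derivatives).
    """
    system, n_e = _prepare_system(model, exps, input_bounds)
    if isinstance(caps, int):
        caps = [caps] * model.n_y
    caps = list(caps)
    if len(caps) != model.n_y:
        raise ValueError(f"{len(caps)} caps for {model.n_y} outputs")
    O = build_obs_matrix(system, caps * n_e)
    report = classify_variables(O, seed, trials, mode="generic")
    report.caveats.append(CAVEAT_CAPPED)
    return report
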