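"""State augmentation and symbolic observability-identifiability matrices.

Unknown parameters are treated as constant extra states, so joint structural
identifiability and observability reduce to a single rank test on the
Jacobian of the stacked output Lie derivatives with respect to the augmented
state.  Lie derivatives honour per-input truncation of the input-derivative
chain: with a derivative bound ``d``, every ``u^(j)`` with ``j > d`` is
identically zero.
"""

from __future__ import annotations

import dataclasses
import json
import math
from typing import Sequence

import sympy as sp

from .model_io import (
    GENERIC,
    ExperimentSet,
    InputSpec,
    ModelError,
    ModelSpec,
    input_deriv_order,
    input_deriv_symbol,
)

__all__ = [
    "AugmentedSystem",
    "ObsMatrix",
    "augment",
    "lie_derivative",
    "min_derivatives",
    "build_obs_matrix",
    "replicate_for_experiments",
    "lift_unknown_inputs",
]


@dataclasses.dataclass
class AugmentedSystem:
    """Augmented system x~ = [states...; parameters...; lifted inputs...].

    Dynamics rows for parameter entries are identically zero.  ``output_tags``
    records ``(experiment_index, output_index)`` per output; single-experiment
    systems use experiment index 0 throughout.
    """

    vars: list[sp.Symbol]
    dynamics: list[sp.Expr]
    outputs: list[sp.Expr]
    input_specs: list[InputSpec]
    n_states: int
    n_params: int
    n_lifted: int = 0
    n_e: int = 1
    output_tags: list[tuple[int, int]] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.output_tags:
            self.output_tags = [(0, i) for i in range(len(self.outputs))]
        if len(self.vars) != len(self.dynamics):
            raise ValueError("vars/dynamics length mismatch")
        if len(self.vars) != self.n_states + self.n_params + self.n_lifted:
            raise ValueError("inconsistent augmented dimensions")

    @property
    def n_xt(self) -> int:
        return len(self.vars)

    @property
    def n_outputs(self) -> int:
        return len(self.outputs)


def augment(model: ModelSpec) -> AugmentedSystem:
    """Append unknown parameters as constant states (x~ = [x; theta]).

    Known constants are substituted into the equations, so the augmented
    system depends only on augmented variables and input symbols.
    """
    model.validate()
    const = dict(model.constants)
    dyn = [sp.sympify(e).xreplace(const) for e in model.dynamics]
    outs = [sp.sympify(e).xreplace(const) for e in model.outputs]
    return AugmentedSystem(
        vars=list(model.states) + list(model.params_unknown),
        dynamics=dyn + [sp.Integer(0)] * model.n_theta,
        outputs=outs,
        input_specs=[dataclasses.replace(i) for i in model.inputs],
        n_states=model.n_x,
        n_params=model.n_theta,
    )


def lie_derivative(
    expr: sp.Expr,
    system: AugmentedSystem,
    input_specs: Sequence[InputSpec] | None = None,
) -> sp.Expr:
    """One Lie derivative of ``expr`` along the augmented vector field.

    Returns ``d expr/d x~ . f~  +  sum_j d expr/d u^(j) . u^(j+1)``, where
    ``u^(j+1)`` is replaced by 0 whenever ``j+1`` exceeds the input's
    ``max_nonzero_deriv`` bound.
    """
    specs = list(input_specs) if input_specs is not None else system.input_specs
    expr = sp.sympify(expr)
    out = sp.Integer(0)
    free = expr.free_symbols
    for v, f in zip(system.vars, system.dynamics):
        if v in free:
            out += sp.diff(expr, v) * f
    for spec in specs:
        bound = spec.max_nonzero_deriv
        for s in free:
            j = input_deriv_order(s, spec.name)
            if j is None:
                continue
            if bound != GENERIC and j + 1 > bound:
                continue  # u^(j+1) == 0 under the truncation assumption
            out += sp.diff(expr, s) * input_deriv_symbol(spec.name, j + 1)
    return out


def min_derivatives(n_x: int, n_theta: int, n_y: int, n_e: int = 1) -> int:
    """Smallest derivative count at which the stacked matrix can be full rank.

    ``ceil((n_e*n_x + n_theta - n_e*n_y) / (n_e*n_y))``, clamped at 0; at a
    single experiment this is ``ceil((n_x + n_theta - n_y) / n_y)``.
    """
    if n_y <= 0:
        raise ValueError("n_y must be positive")
    if n_x <= 0 or n_e <= 0 or n_theta < 0:
        raise ValueError("n_x and n_e must be positive, n_theta non-negative")
    nd = math.ceil((n_e * n_x + n_theta - n_e * n_y) / (n_e * n_y))
    return max(nd, 0)


@dataclasses.dataclass
class ObsMatrix:
    """Symbolic observability-identifiability matrix with labelled rows/columns.

    Rows are grouped per experiment, per output, by increasing derivative
    order; ``row_labels`` holds ``(experiment, output_index, derivative_order)``
    triples and ``derivs_used`` the per-output derivative counts.
    """

    entries: sp.Matrix
    row_labels: list[tuple[int, int, int]]
    col_labels: list[str]
    derivs_used: list[int]

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape

    def to_json(self) -> str:
        return json.dumps(
            {
                "rows": self.entries.rows,
                "cols": self.entries.cols,
                "row_labels": self.row_labels,
                "col_labels": self.col_labels,
                "derivs_used": self.derivs_used,
                "entries": [
                    [sp.sstr(self.entries[i, j]) for j in range(self.entries.cols)]
                    for i in range(self.entries.rows)
                ],
            },
            indent=2,
        )

    def specialized(self, point: dict[sp.Symbol, sp.Expr]) -> "ObsMatrix":
        """Same matrix with a substitution applied entrywise."""
        return ObsMatrix(
            entries=self.entries.xreplace(point),
            row_labels=list(self.row_labels),
            col_labels=list(self.col_labels),
            derivs_used=list(self.derivs_used),
        )


def lie_chain(system: AugmentedSystem, output_index: int, order: int) -> list[sp.Expr]:
    """Output ``output_index`` and its Lie derivatives up to ``order``."""
    chain = [system.outputs[output_index]]
    for _ in range(order):
        chain.append(lie_derivative(chain[-1], system))
    return chain


def build_obs_matrix(
    system: AugmentedSystem,
    derivs: Sequence[int] | int,
    input_specs: Sequence[InputSpec] | None = None,
    simplify: bool = False,
) -> ObsMatrix:
    """Stack Jacobians of outputs and their Lie derivatives w.r.t. x~.

    ``derivs`` gives the highest derivative order per output (a scalar is
    broadcast); honouring per-output caps implements (v_1, ..., v_m)-
    identifiability.  Entry simplification is off by default — ranks are
    evaluated numerically, so simplification only affects readability.
    """
    n_out = system.n_outputs
    if isinstance(derivs, int):
        derivs = [derivs] * n_out
    derivs = list(derivs)
    if len(derivs) != n_out:
        raise ValueError(f"{len(derivs)} derivative counts for {n_out} outputs")
    if any(d < 0 for d in derivs):
        raise ValueError("derivative counts must be >= 0")
    specs = list(input_specs) if input_specs is not None else system.input_specs

    rows: list[list[sp.Expr]] = []
    labels: list[tuple[int, int, int]] = []
    for out_idx in range(n_out):
        exp_idx, local_out = system.output_tags[out_idx]
        expr = system.outputs[out_idx]
        for order in range(derivs[out_idx] + 1):
            if order > 0:
                expr = lie_derivative(expr, system, specs)
            row = [sp.diff(expr, v) for v in system.vars]
            if simplify:
                row = [sp.simplify(e) for e in row]
            rows.append(row)
            labels.append((exp_idx, local_out, order))
    return ObsMatrix(
        entries=sp.Matrix(rows),
        row_labels=labels,
        col_labels=[v.name for v in system.vars],
        derivs_used=derivs,
    )


def _tag(name: str, exp_index: int) -> str:
    return f"{name}_e{exp_index + 1}"


def replicate_for_experiments(
    system: AugmentedSystem, exps: ExperimentSet
) -> AugmentedSystem:
    """Replicate states, outputs and inputs per experiment; share parameters.

    Replicas are blocked state-major (all states of experiment 1, then of
    experiment 2, ...), with parameters kept as a single trailing block so
    column labels stay stable for the deletion test.  ``n_e == 1`` with no
    overrides is the identity.
    """
    if system.n_lifted:
        raise ModelError("replicate before lifting unknown inputs, not after")
    if exps.n_e == 1:
        base_inputs = [exps.input_spec_for(s, 0) for s in system.input_specs]
        return dataclasses.replace(system, input_specs=base_inputs)

    states = system.vars[: system.n_states]
    params = system.vars[system.n_states :]
    new_states: list[sp.Symbol] = []
    new_dyn: list[sp.Expr] = []
    new_outputs: list[sp.Expr] = []
    new_tags: list[tuple[int, int]] = []
    new_inputs: list[InputSpec] = []

    for e in range(exps.n_e):
        sub: dict[sp.Symbol, sp.Symbol] = {}
        for s in states:
            sub[s] = sp.Symbol(_tag(s.name, e))
        for spec in system.input_specs:
            replica = exps.input_spec_for(spec, e)
            replica = dataclasses.replace(replica, name=_tag(spec.name, e))
            new_inputs.append(replica)
            # map the base input symbol and any derivative symbols
            sub[spec.symbol] = replica.symbol
            for j in range(1, 13):
                sub[input_deriv_symbol(spec.name, j)] = input_deriv_symbol(
                    replica.name, j
                )
        new_states += [sub[s] for s in states]
        new_dyn += [system.dynamics[i].xreplace(sub) for i in range(system.n_states)]
        for local_out, g in enumerate(system.outputs):
            new_outputs.append(g.xreplace(sub))
            new_tags.append((e, local_out))

    return AugmentedSystem(
        vars=new_states + params,
        dynamics=new_dyn + [sp.Integer(0)] * len(params),
        outputs=new_outputs,
        input_specs=new_inputs,
        n_states=len(new_states),
        n_params=len(params),
        n_e=exps.n_e,
        output_tags=new_tags,
    )


def lift_unknown_inputs(
    system: AugmentedSystem, orders: dict[str, int] | int
) -> AugmentedSystem:
    """Move unknown inputs into the augmented state as derivative chains.

    For each unknown input ``w`` with order ``k``, appends state variables
    ``w, w_d1, ..., w_dk`` with chain dynamics and ``w^(k+1) = 0``.  The
    required order for a conclusive rank is model-dependent, so it is exposed
    as a caller parameter; a full-rank result is sufficient, not necessary.
    """
    unknown = [s for s in system.input_specs if not s.known]
    if isinstance(orders, int):
        orders = {s.name: orders for s in unknown}
    known_requested = [
        n for n in orders if any(s.name == n and s.known for s in system.input_specs)
    ]
    if known_requested:
        raise ModelError(
            f"cannot lift known input(s): {', '.join(sorted(known_requested))}"
        )
    missing = [n for n in orders if not any(s.name == n for s in system.input_specs)]
    if missing:
        raise ModelError(f"unknown input name(s): {', '.join(sorted(missing))}")
    if any(k < 0 for k in orders.values()):
        raise ModelError("lifting order must be >= 0")

    new_vars = list(system.vars)
    new_dyn = list(system.dynamics)
    n_lifted = system.n_lifted
    remaining = []
    for spec in system.input_specs:
        if spec.name not in orders:
            remaining.append(spec)
            continue
        k = orders[spec.name]
        for j in range(k + 1):
            new_vars.append(input_deriv_symbol(spec.name, j))
            nxt = input_deriv_symbol(spec.name, j + 1) if j < k else sp.Integer(0)
            new_dyn.append(nxt)
        n_lifted += k + 1
    return dataclasses.replace(
        system,
        vars=new_vars,
        dynamics=new_dyn,
        input_specs=remaining,
        n_lifted=n_lifted,
    )
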