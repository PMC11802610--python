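"""Declarative ODE model specifications: types, validation, parsing, serialization.

A model is a set of ordinary differential equations

    dx/dt = f(x, u, theta),    y = g(x, u, theta),

with states ``x``, known/unknown inputs ``u``, unknown parameters ``theta``
and known numeric constants.  Models are written in a flat sectioned text
format (see :func:`parse_model`); expressions use standard infix arithmetic
with ``**`` or ``^`` for powers.  Time derivatives of an input ``u`` are
written ``u_d1``, ``u_d2``, ... by convention.
"""

from __future__ import annotations

import dataclasses
import re
from typing import Any, Iterable

import sympy as sp
from sympy.parsing.sympy_parser import (
    convert_xor,
    parse_expr,
    rationalize,
    standard_transformations,
)

__all__ = [
    "GENERIC",
    "ModelError",
    "InputSpec",
    "ModelSpec",
    "ExperimentSet",
    "input_deriv_symbol",
    "input_deriv_order",
    "parse_model",
    "serialize_model",
]

#: Sentinel for an input with no assumed-zero derivatives (fully generic signal).
GENERIC = "generic"

_TRANSFORMATIONS = standard_transformations + (convert_xor, rationalize)

# Whitelisted function names available in model expressions.  The global
# namespace handed to the parser is otherwise empty so that model symbols such
# as ``I``, ``beta`` or ``gamma`` are never shadowed by sympy built-ins.
_FUNCTIONS: dict[str, Any] = {
    name: getattr(sp, name)
    for name in ("sin", "cos", "tan", "tanh", "exp", "log", "sqrt", "Abs", "sign")
}
_FUNCTIONS["pi"] = sp.pi
# names emitted by the parser's own code generation (auto_number/rationalize)
_FUNCTIONS.update(
    {"Integer": sp.Integer, "Float": sp.Float, "Rational": sp.Rational, "Symbol": sp.Symbol}
)

_NAME_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_]*$")
_DERIV_RE_TEMPLATE = r"^{name}_d([1-9][0-9]*)$"


class ModelError(ValueError):
    """Raised for malformed or inconsistent model documents."""


def input_deriv_symbol(name: str, order: int) -> sp.Symbol:
    """Symbol for the ``order``-th time derivative of input ``name``.

    Order 0 is the input itself; higher orders follow the ``u_d<k>``
    naming convention.
    """
    if order < 0:
        raise ValueError("derivative order must be non-negative")
    return sp.Symbol(name if order == 0 else f"{name}_d{order}")


def input_deriv_order(symbol: sp.Symbol, input_name: str) -> int | None:
    """Return the derivative order encoded by ``symbol`` for ``input_name``.

    ``None`` if the symbol does not belong to that input.
    """
    if symbol.name == input_name:
        return 0
    m = re.match(_DERIV_RE_TEMPLATE.format(name=re.escape(input_name)), symbol.name)
    return int(m.group(1)) if m else None


@dataclasses.dataclass
class InputSpec:
    """Declaration of one model input.

    ``max_nonzero_deriv`` bounds the derivative order beyond which the input
    is assumed constant in time: 0 encodes a constant input, ``d`` a
    polynomial of degree ``d``, and :data:`GENERIC` an unconstrained signal.
    """

    name: str
    known: bool = True
    max_nonzero_deriv: int | str = GENERIC
    fixed_function: Any = None

    def __post_init__(self) -> None:
        if not _NAME_RE.match(self.name):
            raise ModelError(f"invalid input name {self.name!r}")
        b = self.max_nonzero_deriv
        if b != GENERIC and (not isinstance(b, int) or b < 0):
            raise ModelError(
                f"input {self.name!r}: max_nonzero_deriv must be a non-negative "
                f"integer or {GENERIC!r}, got {b!r}"
            )
        if self.fixed_function is not None:
            implied = getattr(self.fixed_function, "max_nonzero_deriv", None)
            if implied is not None and b != GENERIC and implied > b:
                raise ModelError(
                    f"input {self.name!r}: fixed function implies derivative "
                    f"order {implied} > declared bound {b}"
                )

    @property
    def symbol(self) -> sp.Symbol:
        return sp.Symbol(self.name)

    def deriv_symbol(self, order: int) -> sp.Symbol:
        return input_deriv_symbol(self.name, order)


def _parse_expr(text: str, allowed: Iterable[sp.Symbol], context: str) -> sp.Expr:
    local = {s.name: s for s in allowed}
    local.update(_FUNCTIONS)
    try:
        expr = parse_expr(
            text,
            local_dict=local,
            global_dict={},
            transformations=_TRANSFORMATIONS,
            evaluate=True,
        )
    except ModelError:
        raise
    except Exception as exc:  # sympy raises a zoo of error types here
        raise ModelError(f"cannot parse expression {text!r} in {context}: {exc}") from exc
    if not isinstance(expr, (sp.Expr, sp.MatrixBase)):
        raise ModelError(f"expression {text!r} in {context} is not scalar")
    extra = sorted(expr.free_symbols - set(allowed), key=str)
    if extra:
        names = ", ".join(s.name for s in extra)
        raise ModelError(f"unknown symbol(s) {names} in {context}: {text!r}")
    return expr


def _parse_number(text: str, context: str) -> sp.Expr:
    expr = _parse_expr(text, (), context)
    if expr.free_symbols:
        raise ModelError(f"{context}: value {text!r} is not numeric")
    return expr


def _expr_eq(a: sp.Expr, b: sp.Expr) -> bool:
    """Mathematical equality: structural match or zero difference."""
    if a == b:
        return True
    try:
        return sp.simplify(a - b) == 0
    except Exception:
        return False


@dataclasses.dataclass(eq=False)
class ModelSpec:
    """A validated ODE model specification.

    Equality is mathematical: serialization may reorder or re-normalize
    expressions, so round-tripped models compare equal even when their
    expression trees differ structurally.
    """

    name: str
    states: list[sp.Symbol]
    params_unknown: list[sp.Symbol]
    constants: dict[sp.Symbol, sp.Expr]
    inputs: list[InputSpec]
    dynamics: list[sp.Expr]
    outputs: list[sp.Expr]
    known_init: dict[sp.Symbol, sp.Expr] = dataclasses.field(default_factory=dict)
    nominal: dict[sp.Symbol, sp.Expr] = dataclasses.field(default_factory=dict)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ModelSpec):
            return NotImplemented
        if (
            self.name != other.name
            or self.states != other.states
            or self.params_unknown != other.params_unknown
            or self.constants != other.constants
            or self.inputs != other.inputs
            or self.known_init != other.known_init
            or self.nominal != other.nominal
            or len(self.dynamics) != len(other.dynamics)
            or len(self.outputs) != len(other.outputs)
        ):
            return False
        return all(
            _expr_eq(a, b)
            for a, b in zip(
                list(self.dynamics) + list(self.outputs),
                list(other.dynamics) + list(other.outputs),
            )
        )

    # -- dimensions ---------------------------------------------------------
    @property
    def n_x(self) -> int:
        return len(self.states)

    @property
    def n_theta(self) -> int:
        return len(self.params_unknown)

    @property
    def n_y(self) -> int:
        return len(self.outputs)

    @property
    def n_u(self) -> int:
        return len(self.inputs)

    # -- symbol bookkeeping -------------------------------------------------
    def input_symbols(self) -> set[sp.Symbol]:
        return {spec.symbol for spec in self.inputs}

    def declared_symbols(self) -> set[sp.Symbol]:
        syms = set(self.states) | set(self.params_unknown) | set(self.constants)
        syms |= self.input_symbols()
        return syms

    def _expression_symbols(self) -> set[sp.Symbol]:
        """All symbols allowed in dynamics/outputs, incl. input derivatives."""
        syms = self.declared_symbols()
        used: set[sp.Symbol] = set()
        for expr in list(self.dynamics) + list(self.outputs):
            used |= expr.free_symbols
        for s in used - syms:
            if any(input_deriv_order(s, spec.name) is not None for spec in self.inputs):
                syms.add(s)
        return syms

    def validate(self) -> None:
        names = [s.name for s in self.states] + [s.name for s in self.params_unknown]
        names += [str(c) for c in self.constants] + [i.name for i in self.inputs]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ModelError(f"duplicate symbol name(s): {', '.join(sorted(dupes))}")
        if not self.states:
            raise ModelError("model has no states")
        if not self.outputs:
            raise ModelError("model has no outputs")
        if len(self.dynamics) != len(self.states):
            raise ModelError(
                f"{len(self.dynamics)} dynamics equations for {len(self.states)} states"
            )
        allowed = self._expression_symbols()
        for state, rhs in zip(self.states, self.dynamics):
            extra = sorted(rhs.free_symbols - allowed, key=str)
            if extra:
                raise ModelError(
                    f"unknown symbol(s) {', '.join(s.name for s in extra)} "
                    f"in dynamics of {state.name}"
                )
        for i, g in enumerate(self.outputs):
            extra = sorted(g.free_symbols - allowed, key=str)
            if extra:
                raise ModelError(
                    f"unknown symbol(s) {', '.join(s.name for s in extra)} in output {i}"
                )
        bad_init = set(self.known_init) - set(self.states)
        if bad_init:
            raise ModelError(
                f"known_init keys not states: {', '.join(sorted(str(s) for s in bad_init))}"
            )
        state_set = set(self.states)
        param_set = set(self.params_unknown)
        for sym in self.nominal:
            if sym in state_set or sym in param_set:
                continue
            if any(input_deriv_order(sym, spec.name) is not None for spec in self.inputs):
                continue
            raise ModelError(f"nominal value for undeclared symbol {sym}")

    def nominal_float(self) -> dict[str, float]:
        return {str(k): float(v) for k, v in self.nominal.items()}


@dataclasses.dataclass
class ExperimentSet:
    """A multi-experiment design: replicated states/outputs/inputs, shared parameters.

    ``per_experiment`` holds one override mapping per replicate with optional
    keys ``"init"`` (state name -> value) and ``"inputs"`` (input name ->
    :class:`InputSpec` or field overrides).  Parameters are never replicated.
    """

    n_e: int
    per_experiment: list[dict] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_e < 1:
            raise ModelError("n_e must be >= 1")
        if not self.per_experiment:
            self.per_experiment = [{} for _ in range(self.n_e)]
        if len(self.per_experiment) != self.n_e:
            raise ModelError(
                f"per_experiment has {len(self.per_experiment)} entries for n_e={self.n_e}"
            )

    def input_spec_for(self, base: InputSpec, exp_index: int) -> InputSpec:
        """Resolve the input spec for replicate ``exp_index`` (0-based)."""
        override = self.per_experiment[exp_index].get("inputs", {}).get(base.name)
        if override is None:
            return dataclasses.replace(base)
        if isinstance(override, InputSpec):
            return dataclasses.replace(override, name=base.name)
        return dataclasses.replace(base, **override)


# ---------------------------------------------------------------------------
# Text format
# ---------------------------------------------------------------------------

_SECTIONS = (
    "model",
    "states",
    "params",
    "constants",
    "inputs",
    "dynamics",
    "outputs",
    "init",
    "nominal",
)


def _split_sections(text: str) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    current: list[str] | None = None
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            name = line[1:-1].strip().lower()
            if name not in _SECTIONS:
                raise ModelError(f"line {lineno}: unknown section [{name}]")
            if name in sections:
                raise ModelError(f"line {lineno}: duplicate section [{name}]")
            current = sections.setdefault(name, [])
        elif current is None:
            raise ModelError(f"line {lineno}: content before any section header")
        else:
            current.append(line)
    return sections


def _parse_input_line(line: str) -> InputSpec:
    parts = line.split()
    name = parts[0]
    known = True
    bound: int | str = GENERIC
    for tok in parts[1:]:
        if tok == "unknown":
            known = False
        elif tok == "known":
            known = True
        elif tok.startswith("deriv="):
            val = tok.split("=", 1)[1]
            bound = GENERIC if val == GENERIC else int(val)
        else:
            raise ModelError(f"unrecognized input attribute {tok!r} for input {name!r}")
    return InputSpec(name=name, known=known, max_nonzero_deriv=bound)


def parse_model(text: str) -> ModelSpec:
    """Parse a sectioned model document into a validated :class:`ModelSpec`.

    Sections: ``[model]`` (``name = ...``), ``[states]``, ``[params]``,
    ``[constants]``, ``[inputs]``, ``[dynamics]`` (``state = expr`` lines),
    ``[outputs]`` (``label = expr`` lines), ``[init]``, ``[nominal]``.
    Symbol classification is complete after parsing; ordering follows file
    order.  ``#`` starts a comment.
    """
    sections = _split_sections(text)
    for required in ("states", "dynamics", "outputs"):
        if required not in sections:
            raise ModelError(f"missing required section [{required}]")

    name = "model"
    for line in sections.get("model", []):
        key, _, val = line.partition("=")
        if key.strip() == "name":
            name = val.strip()

    def bare_symbols(section: str) -> list[sp.Symbol]:
        out = []
        for line in sections.get(section, []):
            if not _NAME_RE.match(line):
                raise ModelError(f"invalid symbol name {line!r} in [{section}]")
            out.append(sp.Symbol(line))
        return out

    states = bare_symbols("states")
    params = bare_symbols("params")

    constants: dict[sp.Symbol, sp.Expr] = {}
    for line in sections.get("constants", []):
        key, eq, val = line.partition("=")
        if not eq:
            raise ModelError(f"[constants] line {line!r} is not 'name = value'")
        constants[sp.Symbol(key.strip())] = _parse_number(val.strip(), "[constants]")

    inputs = [_parse_input_line(line) for line in sections.get("inputs", [])]

    spec = ModelSpec(
        name=name,
        states=states,
        params_unknown=params,
        constants=constants,
        inputs=inputs,
        dynamics=[],
        outputs=[],
    )

    allowed = spec.declared_symbols()
    # Input derivative symbols are legal in expressions up to a generous order.
    for inp in inputs:
        hi = 12 if inp.max_nonzero_deriv == GENERIC else inp.max_nonzero_deriv
        for j in range(1, hi + 1):
            allowed.add(input_deriv_symbol(inp.name, j))

    rhs_by_state: dict[sp.Symbol, sp.Expr] = {}
    for line in sections["dynamics"]:
        key, eq, val = line.partition("=")
        if not eq:
            raise ModelError(f"[dynamics] line {line!r} is not 'state = expression'")
        sym = sp.Symbol(key.strip())
        if sym not in set(states):
            raise ModelError(f"dynamics given for non-state {sym}")
        if sym in rhs_by_state:
            raise ModelError(f"duplicate dynamics for state {sym}")
        rhs_by_state[sym] = _parse_expr(val.strip(), allowed, f"dynamics of {sym}")
    missing = [s for s in states if s not in rhs_by_state]
    if missing:
        raise ModelError(
            f"missing dynamics for state(s): {', '.join(s.name for s in missing)}"
        )
    spec.dynamics = [rhs_by_state[s] for s in states]

    for line in sections["outputs"]:
        key, eq, val = line.partition("=")
        expr_text = val.strip() if eq else key.strip()
        spec.outputs.append(_parse_expr(expr_text, allowed, "[outputs]"))

    for line in sections.get("init", []):
        key, eq, val = line.partition("=")
        if not eq:
            raise ModelError(f"[init] line {line!r} is not 'state = value'")
        spec.known_init[sp.Symbol(key.strip())] = _parse_number(val.strip(), "[init]")

    for line in sections.get("nominal", []):
        key, eq, val = line.partition("=")
        if not eq:
            raise ModelError(f"[nominal] line {line!r} is not 'name = value'")
        spec.nominal[sp.Symbol(key.strip())] = _parse_number(val.strip(), "[nominal]")

    spec.validate()
    return spec


def serialize_model(model: ModelSpec) -> str:
    """Render a :class:`ModelSpec` back to its text form.

    Round-trips: ``parse_model(serialize_model(m)) == m``.
    """
    lines = ["[model]", f"name = {model.name}", "", "[states]"]
    lines += [s.name for s in model.states]
    if model.params_unknown:
        lines += ["", "[params]"] + [s.name for s in model.params_unknown]
    if model.constants:
        lines += ["", "[constants]"]
        lines += [f"{k} = {sp.sstr(v)}" for k, v in model.constants.items()]
    if model.inputs:
        lines += ["", "[inputs]"]
        for inp in model.inputs:
            toks = [inp.name, "known" if inp.known else "unknown"]
            toks.append(f"deriv={inp.max_nonzero_deriv}")
            lines.append(" ".join(toks))
    lines += ["", "[dynamics]"]
    lines += [f"{s.name} = {sp.sstr(e)}" for s, e in zip(model.states, model.dynamics)]
    lines += ["", "[outputs]"]
    lines += [f"y{i + 1} = {sp.sstr(g)}" for i, g in enumerate(model.outputs)]
    if model.known_init:
        lines += ["", "[init]"]
        lines += [f"{k} = {sp.sstr(v)}" for k, v in model.known_init.items()]
    if model.nominal:
        lines += ["", "[nominal]"]
        lines += [f"{k} = {sp.sstr(v)}" for k, v in model.nominal.items()]
    return "\n".join(lines) + "\n"


def model_to_dict(model: ModelSpec) -> dict:
    """JSON-friendly view of a model (for reports; not a parser input)."""
    return {
        "name": model.name,
        "states": [s.name for s in model.states],
        "params_unknown": [s.name for s in model.params_unknown],
        "constants": {str(k): sp.sstr(v) for k, v in model.constants.items()},
        "inputs": [
            {
                "name": i.name,
                "known": i.known,
                "max_nonzero_deriv": i.max_nonzero_deriv,
            }
            for i in model.inputs
        ],
        "dynamics": [sp.sstr(e) for e in model.dynamics],
        "outputs": [sp.sstr(e) for e in model.outputs],
        "known_init": {str(k): sp.sstr(v) for k, v in model.known_init.items()},
        "nominal": {str(k): sp.sstr(v) for k, v in model.nominal.items()},
    }
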