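"""Execution engine for enzymatic numerical P systems (ENPS).

An ENPS is a cell-like P system whose objects are named numerical
variables placed in a rooted tree of membranes.  Each membrane carries an
ordered list of programs; a program is a production function (an
arithmetic expression over variables), an optional enzyme variable that
gates execution, and a repartition protocol that splits the produced
value among target variables proportionally to non-negative
coefficients.

A program is applicable at time t when it has no enzyme, or when the
enzyme's value compares greater (strict) or greater-or-equal
(non-strict) against the minimum of its production operands' values; a
constant (operand-free) production compares the enzyme against 0.  All
applicable programs of the active membranes fire simultaneously against
the pre-step configuration.  Repartition targets of fired programs are
reset to 0 and then receive the summed increments in program declaration
order, so a single firing rule overwrites its target while several rules
targeting one variable accumulate.  Under the ``consuming`` policy the
production operands of fired programs are additionally reset to 0 (the
classical numerical-P-system behaviour); under ``non-consuming`` they
keep their values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .errors import EvaluationError, ModelError, NonHaltingError, RepartitionError
from .expressions import Expression

__all__ = [
    "Program",
    "Membrane",
    "ENPSystem",
    "Configuration",
    "ExecutionPolicy",
    "ScheduleEntry",
    "RunResult",
    "is_applicable",
    "evaluate_production",
    "distribute",
    "apply_step",
    "run_to_halt",
]

STRICT = "strict"
NON_STRICT = "non-strict"
STAGED = "staged"
ALL_PARALLEL = "all-parallel"
CONSUMING = "consuming"
NON_CONSUMING = "non-consuming"


@dataclass(frozen=True)
class Program:
    """One ENPS rule: production | enzyme -> c1|v1 + c2|v2 + ...

    ``repartition`` is an ordered list of ``(coefficient, target)`` pairs;
    coefficients are non-negative and at least one pair is required.  The
    enzyme, when present, must be distinct from every production operand
    and every repartition target.
    """

    name: str
    production: Expression
    repartition: Tuple[Tuple[float, str], ...]
    enzyme: Optional[str] = None
    comparison: str = NON_STRICT

    def __post_init__(self):
        if isinstance(self.production, str):
            object.__setattr__(self, "production", Expression(self.production))
        rep = tuple((float(c), str(t)) for c, t in self.repartition)
        object.__setattr__(self, "repartition", rep)
        if not rep:
            raise ModelError(f"program {self.name!r}: repartition protocol is empty")
        for c, t in rep:
            if not c >= 0.0:
                raise ModelError(
                    f"program {self.name!r}: repartition coefficient {c} for "
                    f"{t!r} is negative"
                )
        if self.comparison not in (STRICT, NON_STRICT):
            raise ModelError(
                f"program {self.name!r}: comparison must be "
                f"{STRICT!r} or {NON_STRICT!r}, got {self.comparison!r}"
            )
        if self.enzyme is not None:
            if self.enzyme in self.production.operands:
                raise ModelError(
                    f"program {self.name!r}: enzyme {self.enzyme!r} appears "
                    "among the production operands"
                )
            if any(t == self.enzyme for _, t in rep):
                raise ModelError(
                    f"program {self.name!r}: enzyme {self.enzyme!r} appears "
                    "among the repartition targets"
                )

    @property
    def operands(self) -> Tuple[str, ...]:
        return self.production.operands

    @property
    def targets(self) -> Tuple[str, ...]:
        return tuple(t for _, t in self.repartition)


@dataclass
class Membrane:
    """A membrane: label, parent link (None for the skin), variables with
    their initial values, the subset flagged as enzymes, and the ordered
    program list."""

    label: str
    parent: Optional[str]
    variables: Dict[str, float] = field(default_factory=dict)
    enzymes: Tuple[str, ...] = ()
    programs: List[Program] = field(default_factory=list)


class ENPSystem:
    """A full ENPS: membrane tree, variables, enzymes and programs.

    Validated on construction: the parent links must form a tree over the
    given membranes with a single root (the skin), variable names must be
    unique system-wide, enzymes must belong to their own membrane's
    variable set, and every name referenced by any program (operand,
    enzyme, repartition target) must resolve to a declared variable.
    Programs may read and write variables of any membrane; membranes
    partition ownership, not visibility.
    """

    def __init__(self, membranes: Sequence[Membrane]):
        self.membranes: List[Membrane] = list(membranes)
        self._by_label: Dict[str, Membrane] = {}
        self._validate()

    # -- structure ---------------------------------------------------------

    def _validate(self) -> None:
        if not self.membranes:
            raise ModelError("system has no membranes")
        for mb in self.membranes:
            if mb.label in self._by_label:
                raise ModelError(f"duplicate membrane label {mb.label!r}")
            self._by_label[mb.label] = mb
        roots = [mb for mb in self.membranes if mb.parent is None]
        if len(roots) != 1:
            raise ModelError(
                f"membrane hierarchy must have exactly one root (skin); "
                f"found {len(roots)}"
            )
        self._skin = roots[0].label
        for mb in self.membranes:
            if mb.parent is not None and mb.parent not in self._by_label:
                raise ModelError(
                    f"membrane {mb.label!r} references unknown parent {mb.parent!r}"
                )
        # acyclicity: every membrane must reach the root via parent links
        for mb in self.membranes:
            seen = set()
            cur: Optional[str] = mb.label
            while cur is not None:
                if cur in seen:
                    raise ModelError(f"membrane hierarchy has a cycle through {cur!r}")
                seen.add(cur)
                cur = self._by_label[cur].parent

        self._var_home: Dict[str, str] = {}
        for mb in self.membranes:
            for name in mb.variables:
                if name in self._var_home:
                    raise ModelError(
                        f"variable {name!r} declared in membranes "
                        f"{self._var_home[name]!r} and {mb.label!r}"
                    )
                self._var_home[name] = mb.label
            for enz in mb.enzymes:
                if enz not in mb.variables:
                    raise ModelError(
                        f"enzyme {enz!r} is not a variable of membrane {mb.label!r}"
                    )
        for mb in self.membranes:
            for prog in mb.programs:
                for ref in prog.operands:
                    if ref not in self._var_home:
                        raise ModelError(
                            f"program {prog.name!r} (membrane {mb.label!r}) "
                            f"reads undeclared variable {ref!r}"
                        )
                if prog.enzyme is not None and prog.enzyme not in self._var_home:
                    raise ModelError(
                        f"program {prog.name!r} (membrane {mb.label!r}) "
                        f"references undeclared enzyme {prog.enzyme!r}"
                    )
                for _, tgt in prog.repartition:
                    if tgt not in self._var_home:
                        raise ModelError(
                            f"program {prog.name!r} (membrane {mb.label!r}) "
                            f"targets undeclared variable {tgt!r}"
                        )

    # -- accessors ---------------------------------------------------------

    @property
    def m(self) -> int:
        """Number of membranes."""
        return len(self.membranes)

    @property
    def labels(self) -> Tuple[str, ...]:
        return tuple(mb.label for mb in self.membranes)

    @property
    def skin(self) -> str:
        return self._skin

    def membrane(self, label: str) -> Membrane:
        try:
            return self._by_label[label]
        except KeyError:
            raise ModelError(f"no membrane labelled {label!r}") from None

    def variable_membrane(self, name: str) -> str:
        """Label of the membrane owning ``name``."""
        try:
            return self._var_home[name]
        except KeyError:
            raise ModelError(f"no variable named {name!r}") from None

    @property
    def variables(self) -> Dict[str, float]:
        """All variables with their initial values, declaration order."""
        out: Dict[str, float] = {}
        for mb in self.membranes:
            out.update(mb.variables)
        return out

    @property
    def enzymes(self) -> Tuple[str, ...]:
        return tuple(e for mb in self.membranes for e in mb.enzymes)

    @property
    def programs(self) -> List[Program]:
        return [p for mb in self.membranes for p in mb.programs]

    def initial_configuration(self) -> "Configuration":
        return Configuration(values=dict(self.variables), step_index=0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ENPSystem):
            return NotImplemented
        return [
            (mb.label, mb.parent, mb.variables, mb.enzymes, mb.programs)
            for mb in self.membranes
        ] == [
            (mb.label, mb.parent, mb.variables, mb.enzymes, mb.programs)
            for mb in other.membranes
        ]


@dataclass
class Configuration:
    """Values of every declared variable at a given step."""

    values: Dict[str, float]
    step_index: int = 0

    def copy(self) -> "Configuration":
        return Configuration(values=dict(self.values), step_index=self.step_index)


@dataclass(frozen=True)
class ExecutionPolicy:
    """How the engine schedules and fires programs.

    mode:
        ``staged`` (an explicit membrane schedule drives each step) or
        ``all-parallel`` (every membrane is active every step).
    consumption:
        ``consuming`` resets production operands of fired programs to 0
        (classical NPS); ``non-consuming`` leaves them untouched.
    max_steps:
        guard for all-parallel runs; exhaustion raises NonHaltingError.
    halt_variable / halt_threshold:
        optional stop condition: halt once the variable's value is >= the
        threshold.
    halt_on_fixed_point:
        in all-parallel mode, also halt when a step leaves every variable
        unchanged.
    """

    mode: str = STAGED
    consumption: str = NON_CONSUMING
    max_steps: int = 1000
    halt_variable: Optional[str] = None
    halt_threshold: float = 1.0
    halt_on_fixed_point: bool = False

    def __post_init__(self):
        if self.mode not in (STAGED, ALL_PARALLEL):
            raise ModelError(f"unknown execution mode {self.mode!r}")
        if self.consumption not in (CONSUMING, NON_CONSUMING):
            raise ModelError(f"unknown consumption policy {self.consumption!r}")
        if not (isinstance(self.max_steps, int) and self.max_steps >= 1):
            raise ModelError("max_steps must be a positive integer")


@dataclass(frozen=True)
class ScheduleEntry:
    """One staged step: the membranes to activate and, optionally, an
    explicit subset of program names within them."""

    membranes: Tuple[str, ...]
    programs: Optional[frozenset] = None
    label: Optional[str] = None


@dataclass
class RunResult:
    configuration: Configuration
    steps_executed: int
    fired_counts: List[int]
    trace: Optional[List[Tuple[int, Dict[str, float]]]] = None


# ---------------------------------------------------------------------------
# operations


def is_applicable(program: Program, config: Configuration) -> bool:
    """Enzyme gate: true iff the program has no enzyme, or the enzyme value
    compares (>= non-strict, > strict) against the minimum operand value.
    An operand-free (constant) production compares the enzyme against 0."""
    if program.enzyme is None:
        return True
    try:
        enzyme_value = config.values[program.enzyme]
        ops = program.operands
        floor = min(config.values[o] for o in ops) if ops else 0.0
    except KeyError as exc:
        raise ModelError(
            f"program {program.name!r}: unresolved variable reference {exc}"
        ) from exc
    if program.comparison == STRICT:
        return enzyme_value > floor
    return enzyme_value >= floor


def evaluate_production(program: Program, config: Configuration) -> float:
    """Value of the production function on the current configuration."""
    return program.production.evaluate(config.values)


def distribute(
    amount: float, repartition: Iterable[Tuple[float, str]]
) -> Dict[str, float]:
    """Split ``amount`` among targets proportionally to coefficients.

    Target v_k receives amount * c_k / sum(c).  A zero coefficient sum is
    legal only for a zero amount (every increment is then 0)."""
    rep = [(float(c), t) for c, t in repartition]
    if not rep:
        raise ModelError("repartition protocol is empty")
    total = sum(c for c, _ in rep)
    out: Dict[str, float] = {}
    if total == 0.0:
        if amount != 0.0:
            raise RepartitionError(
                f"cannot distribute non-zero amount {amount} over zero "
                "coefficient sum"
            )
        for _, t in rep:
            out.setdefault(t, 0.0)
        return out
    for c, t in rep:
        out[t] = out.get(t, 0.0) + amount * (c / total)
    return out


def _select_programs(
    system: ENPSystem,
    active_membranes: Optional[Iterable[str]],
    program_names: Optional[frozenset],
) -> List[Tuple[str, Program]]:
    if active_membranes is None:
        labels = list(system.labels)
    else:
        labels = list(active_membranes)
        unknown = [l for l in labels if l not in system.labels]
        if unknown:
            raise ModelError(f"unknown membrane label(s) {unknown!r} in schedule")
    selected = []
    for label in labels:
        for prog in system.membrane(label).programs:
            if program_names is None or prog.name in program_names:
                selected.append((label, prog))
    return selected


def apply_step(
    system: ENPSystem,
    config: Configuration,
    policy: ExecutionPolicy,
    active_membranes: Optional[Iterable[str]] = None,
    program_names: Optional[frozenset] = None,
) -> Tuple[Configuration, int]:
    """One synchronous step over the active membranes.

    Every applicable program evaluates its production against the
    pre-step configuration; repartition targets of fired programs are
    reset to 0 and receive the summed increments in declaration order;
    under the consuming policy the operands of fired programs are reset
    to 0 first.  Returns the new configuration (step_index + 1) and the
    number of programs that fired.
    """
    fired: List[Tuple[str, Program, Dict[str, float]]] = []
    for label, prog in _select_programs(system, active_membranes, program_names):
        if not is_applicable(prog, config):
            continue
        try:
            amount = evaluate_production(prog, config)
            increments = distribute(amount, prog.repartition)
        except (EvaluationError, RepartitionError) as exc:
            raise type(exc)(
                f"membrane {label!r}, program {prog.name!r}: {exc}"
            ) from exc
        fired.append((label, prog, increments))

    new_values = dict(config.values)
    if policy.consumption == CONSUMING:
        for _, prog, _inc in fired:
            for op in prog.operands:
                new_values[op] = 0.0
    for _, prog, _inc in fired:
        for _, tgt in prog.repartition:
            new_values[tgt] = 0.0
    for _, _prog, increments in fired:
        for tgt, inc in increments.items():
            new_values[tgt] += inc
    return Configuration(new_values, config.step_index + 1), len(fired)


def _halted(policy: ExecutionPolicy, config: Configuration) -> bool:
    if policy.halt_variable is None:
        return False
    try:
        value = config.values[policy.halt_variable]
    except KeyError as exc:
        raise ModelError(
            f"halt variable {policy.halt_variable!r} is not declared"
        ) from exc
    return value >= policy.halt_threshold


def run_to_halt(
    system: ENPSystem,
    policy: ExecutionPolicy,
    schedule: Optional[Sequence[ScheduleEntry]] = None,
    config: Optional[Configuration] = None,
    record_trace: bool = False,
) -> RunResult:
    """Run the system to a halting configuration.

    In staged mode, ``schedule`` (non-empty) is applied entry by entry;
    the run stops early if the halt variable reaches its threshold.  In
    all-parallel mode, steps repeat until the halt variable triggers, no
    program fires, or (if enabled) a fixed point is reached; exhausting
    ``max_steps`` raises :class:`NonHaltingError` rather than silently
    truncating.
    """
    if config is None:
        config = system.initial_configuration()
    else:
        declared = set(system.variables)
        if set(config.values) != declared:
            raise ModelError(
                "configuration domain does not match the system's variables"
            )
        config = config.copy()
    trace: Optional[List[Tuple[int, Dict[str, float]]]] = None
    if record_trace:
        trace = [(config.step_index, dict(config.values))]
    fired_counts: List[int] = []

    if policy.mode == STAGED:
        if not schedule:
            raise ModelError("staged mode requires a non-empty schedule")
        steps = 0
        for entry in schedule:
            config, fired = apply_step(
                system, config, policy, entry.membranes, entry.programs
            )
            steps += 1
            fired_counts.append(fired)
            if trace is not None:
                trace.append((config.step_index, dict(config.values)))
            if _halted(policy, config):
                break
        return RunResult(config, steps, fired_counts, trace)

    # all-parallel
    steps = 0
    while True:
        if _halted(policy, config):
            return RunResult(config, steps, fired_counts, trace)
        if steps >= policy.max_steps:
            raise NonHaltingError(
                f"no halting configuration within max_steps={policy.max_steps}",
                steps_executed=steps,
                configuration=config,
            )
        new_config, fired = apply_step(system, config, policy)
        if fired == 0:
            return RunResult(config, steps, fired_counts, trace)
        steps += 1
        fired_counts.append(fired)
        if trace is not None:
            trace.append((new_config.step_index, dict(new_config.values)))
        if policy.halt_on_fixed_point and new_config.values == config.values:
            return RunResult(new_config, steps, fired_counts, trace)
        config = new_config
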