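"""Engine semantics: applicability, production evaluation, repartition,
synchronous stepping, halting, and equivalence with a brute-force
one-step reference on random small systems."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edenp import (
    Configuration,
    ExecutionPolicy,
    Expression,
    ModelError,
    NonHaltingError,
    Program,
    RepartitionError,
    ScheduleEntry,
    apply_step,
    distribute,
    evaluate_production,
    is_applicable,
    run_to_halt,
)
from edenp.errors import EvaluationError, ExpressionError

from conftest import all_parallel, one_membrane_system


def prog(production, repartition, enzyme=None, comparison="non-strict", name="p"):
    return Program(
        name=name,
        production=production,
        repartition=tuple(repartition),
        enzyme=enzyme,
        comparison=comparison,
    )


def config(**values):
    return Configuration(values=dict(values))


class TestApplicability:
    def test_enzyme_above_all_operands_fires(self):
        # seed enzyme at 256 dominates any 8-bit intensity
        p = prog("x", [(1, "y")], enzyme="e")
        assert is_applicable(p, config(x=255.0, y=0.0, e=256.0))

    def test_enzyme_below_operand_minimum_blocks(self):
        p = prog("ed1 + 2*ed2", [(1, "y")], enzyme="E")
        assert not is_applicable(p, config(ed1=0.0, ed2=1.0, y=0.0, E=-0.1))

    def test_negative_sentinel_operand_lowers_the_gate(self):
        p = prog("0*ed1 + 0*ed3", [(1, "y")], enzyme="E")
        assert is_applicable(p, config(ed1=0.0, ed3=-256.0, y=0.0, E=-0.1))

    def test_enzyme_free_program_is_unconditional(self):
        p = prog("x", [(1, "y")])
        assert is_applicable(p, config(x=-1e9, y=0.0))

    def test_strict_vs_non_strict_at_equality(self):
        values = dict(x=1.0, y=0.0, e=1.0)
        assert is_applicable(prog("x", [(1, "y")], enzyme="e"), config(**values))
        assert not is_applicable(
            prog("x", [(1, "y")], enzyme="e", comparison="strict"), config(**values)
        )

    def test_constant_production_compares_enzyme_against_zero(self):
        p = prog("0", [(1, "y")], enzyme="e")
        assert is_applicable(p, config(y=5.0, e=0.0))
        assert not is_applicable(p, config(y=5.0, e=-0.5))

    def test_unresolved_enzyme_is_a_model_error(self):
        p = prog("x", [(1, "y")], enzyme="missing")
        with pytest.raises(ModelError):
            is_applicable(p, config(x=0.0, y=0.0))


class TestProduction:
    @pytest.mark.parametrize(
        "source, values, expected",
        [
            ("ed1 + 2*ed2", dict(ed1=0.0, ed2=1.0), 2.0),
            ("sqrt(gx*gx + gy*gy)", dict(gx=3.0, gy=4.0), 5.0),
            ("a - 2*b + c**2", dict(a=1.0, b=0.5, c=3.0), 9.0),
            ("-a + 2*(b - a)", dict(a=1.0, b=4.0), 5.0),
            ("0", {}, 0.0),
        ],
    )
    def test_expression_values(self, source, values, expected):
        p = prog(source, [(1, "out")])
        assert evaluate_production(p, config(out=0.0, **values)) == expected

    def test_zero_sum_mask_on_constant_window_produces_zero(self):
        source = "x1 + 2*x2 + x3 - x4 - 2*x5 - x6"
        values = {f"x{k}": 0.75 for k in range(1, 7)}
        p = prog(source, [(1, "gx")])
        assert evaluate_production(p, config(gx=0.0, **values)) == 0.0

    def test_evaluation_is_pure(self):
        c = config(a=3.0, b=0.0)
        evaluate_production(prog("2*a", [(1, "b")]), c)
        assert c.values == {"a": 3.0, "b": 0.0}

    def test_sqrt_of_negative_raises_numerical_error(self):
        p = prog("sqrt(a)", [(1, "b")])
        with pytest.raises(EvaluationError):
            evaluate_production(p, config(a=-1.0, b=0.0))

    @pytest.mark.parametrize(
        "source",
        ["a / b", "a ** b", "a ** -1", "sin(a)", "a if b else 0", "[a]", "a; b", ""],
    )
    def test_grammar_rejects_unsupported_syntax(self, source):
        with pytest.raises(ExpressionError):
            Expression(source)

    def test_operands_are_collected_without_sqrt(self):
        e = Expression("sqrt(gx*gx + gy*gy) + theta")
        assert set(e.operands) == {"gx", "gy", "theta"}

    def test_very_long_linear_chain_parses(self):
        # halting-rule shape: thousands of zero-coefficient terms
        source = " + ".join(f"0*v{k}" for k in range(5000)) + " + 1"
        e = Expression(source)
        assert e.evaluate({f"v{k}": float(k) for k in range(5000)}) == 1.0


class TestDistribute:
    def test_even_two_way_split(self):
        assert distribute(2.0, [(1, "edg"), (1, "ED")]) == {"edg": 1.0, "ED": 1.0}

    def test_proportional_split(self):
        out = distribute(0.6, [(1, "g"), (1, "E")])
        assert out == pytest.approx({"g": 0.3, "E": 0.3})

    def test_zero_amount_zero_coefficients(self):
        assert distribute(0.0, [(0, "gx")]) == {"gx": 0.0}

    def test_zero_coefficients_with_nonzero_amount_raise(self):
        with pytest.raises(RepartitionError):
            distribute(1.0, [(0, "gx"), (0, "gy")])

    def test_empty_repartition_is_a_model_error(self):
        with pytest.raises(ModelError):
            distribute(1.0, [])

    @settings(derandomize=True, max_examples=200)
    @given(
        amount=st.floats(-1e6, 1e6, allow_nan=False),
        coeffs=st.lists(st.floats(0.01, 100.0), min_size=1, max_size=6),
    )
    def test_increments_conserve_the_production_value(self, amount, coeffs):
        rep = [(c, f"v{k}") for k, c in enumerate(coeffs)]
        out = distribute(amount, rep)
        assert sum(out.values()) == pytest.approx(amount, rel=1e-9, abs=1e-12)


class TestProgramInvariants:
    def test_enzyme_cannot_be_an_operand(self):
        with pytest.raises(ModelError):
            prog("e + a", [(1, "b")], enzyme="e")

    def test_enzyme_cannot_be_a_target(self):
        with pytest.raises(ModelError):
            prog("a", [(1, "e")], enzyme="e")

    def test_negative_coefficient_rejected(self):
        with pytest.raises(ModelError):
            prog("a", [(-1, "b")])


class TestApplyStep:
    def test_non_consuming_keeps_operands(self, doubling_system):
        cfg, fired = apply_step(
            doubling_system, doubling_system.initial_configuration(), all_parallel()
        )
        assert fired == 1
        assert cfg.values == {"a": 3.0, "b": 6.0}
        assert cfg.step_index == 1

    def test_consuming_zeroes_operands(self, doubling_system):
        policy = all_parallel(consumption="consuming")
        cfg, fired = apply_step(
            doubling_system, doubling_system.initial_configuration(), policy
        )
        assert cfg.values == {"a": 0.0, "b": 6.0}

    def test_targets_of_fired_rules_are_overwritten(self):
        system = one_membrane_system(
            {"a": 3.0, "b": 99.0}, [prog("2*a", [(1, "b")], name="r")]
        )
        cfg, _ = apply_step(system, system.initial_configuration(), all_parallel())
        assert cfg.values["b"] == 6.0  # reset to 0, then incremented

    def test_untargeted_variables_are_untouched(self):
        system = one_membrane_system(
            {"a": 3.0, "b": 0.0, "c": 42.0}, [prog("2*a", [(1, "b")], name="r")]
        )
        cfg, _ = apply_step(system, system.initial_configuration(), all_parallel())
        assert cfg.values["c"] == 42.0

    def test_increments_to_a_shared_target_are_summed(self):
        system = one_membrane_system(
            {"a": 1.0, "b": 2.0, "t": 0.0},
            [prog("a", [(1, "t")], name="r1"), prog("b", [(1, "t")], name="r2")],
        )
        cfg, fired = apply_step(system, system.initial_configuration(), all_parallel())
        assert fired == 2
        assert cfg.values["t"] == 3.0

    def test_all_rules_read_the_pre_step_configuration(self):
        # r1 writes a, r2 reads a: r2 must still see the old value
        system = one_membrane_system(
            {"a": 1.0, "b": 0.0},
            [prog("10", [(1, "a")], name="r1"), prog("a", [(1, "b")], name="r2")],
        )
        cfg, _ = apply_step(system, system.initial_configuration(), all_parallel())
        assert cfg.values == {"a": 10.0, "b": 1.0}

    def test_blocked_program_contributes_nothing(self):
        system = one_membrane_system(
            {"a": 5.0, "b": 0.0, "e": -1.0},
            [prog("a", [(1, "b")], enzyme="e", name="gated")],
            enzymes=("e",),
        )
        cfg, fired = apply_step(system, system.initial_configuration(), all_parallel())
        assert fired == 0
        assert cfg.values == {"a": 5.0, "b": 0.0, "e": -1.0}

    def test_unknown_membrane_label_rejected(self, doubling_system):
        with pytest.raises(ModelError):
            apply_step(
                doubling_system,
                doubling_system.initial_configuration(),
                all_parallel(),
                active_membranes=["nope"],
            )


class TestRunToHalt:
    def test_halt_variable_stops_the_run(self):
        system = one_membrane_system(
            {"a": 1.0, "halt": 0.0},
            [prog("a + 1", [(1, "a")], name="inc"), prog("a", [(1, "halt")], name="h")],
        )
        policy = all_parallel(halt_variable="halt", halt_threshold=4.0)
        result = run_to_halt(system, policy)
        assert result.configuration.values["halt"] >= 4.0

    def test_fixed_point_halting(self):
        system = one_membrane_system({"a": 5.0}, [prog("a", [(1, "a")], name="id")])
        result = run_to_halt(system, all_parallel(halt_on_fixed_point=True))
        assert result.configuration.values["a"] == 5.0
        assert result.steps_executed == 1

    def test_max_steps_exhaustion_raises_instead_of_truncating(self):
        system = one_membrane_system({"a": 5.0}, [prog("a", [(1, "a")], name="id")])
        with pytest.raises(NonHaltingError):
            run_to_halt(system, all_parallel(max_steps=7))

    def test_zero_program_system_halts_immediately(self):
        system = one_membrane_system({"a": 1.0}, [])
        result = run_to_halt(system, all_parallel())
        assert result.steps_executed == 0
        assert result.fired_counts == []

    def test_staged_mode_requires_a_schedule(self, doubling_system):
        with pytest.raises(ModelError):
            run_to_halt(doubling_system, ExecutionPolicy(mode="staged"))

    def test_staged_schedule_executes_once_per_entry(self, doubling_system):
        schedule = [ScheduleEntry(("s",)), ScheduleEntry(("s",))]
        result = run_to_halt(
            doubling_system, ExecutionPolicy(mode="staged"), schedule=schedule
        )
        assert result.steps_executed == 2
        assert result.configuration.values["b"] == 6.0

    def test_program_name_filter_limits_firing(self):
        system = one_membrane_system(
            {"a": 1.0, "b": 0.0, "c": 0.0},
            [prog("a", [(1, "b")], name="r1"), prog("a", [(1, "c")], name="r2")],
        )
        schedule = [ScheduleEntry(("s",), programs=frozenset(["r1"]))]
        result = run_to_halt(system, ExecutionPolicy(mode="staged"), schedule=schedule)
        assert result.configuration.values == {"a": 1.0, "b": 1.0, "c": 0.0}
        assert result.fired_counts == [1]

    def test_trace_records_every_step(self, doubling_system):
        schedule = [ScheduleEntry(("s",))]
        result = run_to_halt(
            doubling_system,
            ExecutionPolicy(mode="staged"),
            schedule=schedule,
            record_trace=True,
        )
        assert [step for step, _ in result.trace] == [0, 1]
        assert result.trace[0][1] == {"a": 3.0, "b": 0.0}
        assert result.trace[1][1] == {"a": 3.0, "b": 6.0}

    def test_runs_are_deterministic_bit_for_bit(self, rng):
        system, policy = _random_system(rng, n_rules=5, n_vars=8)

        def bounded_trace(steps=10):
            cfg = system.initial_configuration()
            trace = [dict(cfg.values)]
            fired_counts = []
            for _ in range(steps):
                cfg, fired = apply_step(system, cfg, policy)
                trace.append(dict(cfg.values))
                fired_counts.append(fired)
            return trace, fired_counts

        assert bounded_trace() == bounded_trace()  # exact float equality


# ---------------------------------------------------------------------------
# brute-force one-step reference on random small systems


def _random_system(rng, n_rules, n_vars, comparison="non-strict"):
    names = [f"v{k}" for k in range(n_vars)]
    variables = {n: float(np.round(rng.normal(0, 5), 3)) for n in names}
    programs = []
    for r in range(n_rules):
        k = int(rng.integers(1, min(4, n_vars)))  # leave at least one non-operand
        term_vars = list(rng.choice(names, size=k, replace=False))
        coeffs = [float(c) for c in rng.integers(-3, 4, size=k)]
        source = " + ".join(f"{c}*{v}" for c, v in zip(coeffs, term_vars))
        enzyme = None
        candidates = [n for n in names if n not in term_vars]
        if rng.random() < 0.6 and len(candidates) >= 2:
            enzyme = candidates.pop(int(rng.integers(len(candidates))))
        n_targets = min(int(rng.integers(1, 3)), len(candidates))
        targets = list(rng.choice(candidates, size=n_targets, replace=False))
        rep = tuple((float(rng.integers(1, 4)), t) for t in targets)
        programs.append(
            Program(
                name=f"r{r}",
                production=source,
                repartition=rep,
                enzyme=enzyme,
                comparison=comparison,
                # keep the raw pieces for the independent reference
            )
        )
        programs[-1].__dict__["_terms"] = list(zip(coeffs, term_vars))
    system = one_membrane_system(variables, programs)
    policy = all_parallel(
        consumption="consuming" if rng.random() < 0.5 else "non-consuming"
    )
    return system, policy


def _reference_step(system, policy, comparison="non-strict"):
    """Plain-loop re-implementation of one synchronous step."""
    values = dict(system.variables)
    fired = []
    for p in system.programs:
        terms = p.__dict__["_terms"]
        if p.enzyme is not None:
            floor = min(values[v] for _, v in terms)
            ok = values[p.enzyme] > floor if comparison == "strict" else (
                values[p.enzyme] >= floor
            )
            if not ok:
                continue
        amount = 0.0
        for c, v in terms:
            amount = amount + c * values[v]
        total = sum(c for c, _ in p.repartition)
        fired.append((p, {t: amount * (c / total) for c, t in p.repartition}))
    new = dict(values)
    if policy.consumption == "consuming":
        for p, _ in fired:
            for _, v in p.__dict__["_terms"]:
                new[v] = 0.0
    for p, _ in fired:
        for _, t in p.repartition:
            new[t] = 0.0
    for p, inc in fired:
        for t, x in inc.items():
            new[t] += x
    return new, len(fired)


@pytest.mark.parametrize("trial", range(40))
def test_one_step_matches_brute_force_reference(trial):
    rng = np.random.default_rng(1000 + trial)
    system, policy = _random_system(
        rng, n_rules=int(rng.integers(1, 6)), n_vars=int(rng.integers(3, 9))
    )
    expected_values, expected_fired = _reference_step(system, policy)
    cfg, fired = apply_step(system, system.initial_configuration(), policy)
    assert fired == expected_fired
    assert cfg.values == pytest.approx(expected_values, rel=1e-9, abs=1e-12)


def test_engine_conserves_each_rule_production(rng):
    """Per fired rule, distributed increments sum to the production value."""
    for trial in range(20):
        system, policy = _random_system(rng, n_rules=4, n_vars=6)
        cfg = system.initial_configuration()
        for p in system.programs:
            if not is_applicable(p, cfg):
                continue
            amount = evaluate_production(p, cfg)
            incs = distribute(amount, p.repartition)
            assert sum(incs.values()) == pytest.approx(amount, rel=1e-9, abs=1e-12)


def test_gated_rule_never_contributes_anywhere_in_the_trace():
    """Trace inspection: a permanently blocked rule leaves its target flat."""
    system = one_membrane_system(
        {"a": 1.0, "blocked_target": 7.0, "e": -100.0, "ticker": 0.0},
        [
            Program(
                name="gated",
                production="a",
                repartition=((1.0, "blocked_target"),),
                enzyme="e",
            ),
            Program(name="tick", production="ticker + 1", repartition=((1.0, "ticker"),)),
        ],
    )
    policy = all_parallel(halt_variable="ticker", halt_threshold=5.0)
    result = run_to_halt(system, policy, record_trace=True)
    assert all(values["blocked_target"] == 7.0 for _, values in result.trace)
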