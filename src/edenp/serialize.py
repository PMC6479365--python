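"""Model-description files: a small JSON dialect for ENPS systems.

Top-level keys:

``membranes``
    list of ``{"label", "parent", "variables": {name: value},
    "enzymes": [names]}`` (parent ``null`` marks the skin);
``programs``
    list of ``{"membrane", "name", "production", "enzyme",
    "repartition": [[coefficient, target], ...], "comparison"}``;
``policy`` (optional)
    default :class:`~edenp.core.ExecutionPolicy` fields;
``schedule`` (optional)
    list of ``{"membranes": [labels], "programs": [names] | null,
    "label": str | null}``.

Production expressions support ``+ - *``, numeric constants, variable
names, non-negative integer powers and ``sqrt``.  ``parse(write(s))`` is
structurally identical to ``s``; all system invariants are validated at
parse time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Any, Dict, List, Optional

from .core import ENPSystem, ExecutionPolicy, Membrane, Program, ScheduleEntry
from .errors import ModelError

__all__ = ["parse_model", "write_model", "parse_document", "ModelDocument"]


@dataclass
class ModelDocument:
    system: ENPSystem
    policy: Optional[ExecutionPolicy] = None
    schedule: Optional[List[ScheduleEntry]] = None


def _require(mapping: Dict[str, Any], key: str, context: str) -> Any:
    if key not in mapping:
        raise ModelError(f"{context}: missing required key {key!r}")
    return mapping[key]


def _membrane_from_dict(d: Dict[str, Any]) -> Membrane:
    if not isinstance(d, dict):
        raise ModelError(f"membrane entry must be an object, got {type(d).__name__}")
    label = str(_require(d, "label", "membrane"))
    parent = d.get("parent")
    parent = None if parent is None else str(parent)
    variables = _require(d, "variables", f"membrane {label!r}")
    if not isinstance(variables, dict):
        raise ModelError(f"membrane {label!r}: 'variables' must be an object")
    try:
        var_map = {str(k): float(v) for k, v in variables.items()}
    except (TypeError, ValueError) as exc:
        raise ModelError(f"membrane {label!r}: non-numeric initial value: {exc}")
    enzymes = d.get("enzymes", [])
    if not isinstance(enzymes, list):
        raise ModelError(f"membrane {label!r}: 'enzymes' must be a list")
    return Membrane(
        label=label,
        parent=parent,
        variables=var_map,
        enzymes=tuple(str(e) for e in enzymes),
    )


def _program_from_dict(d: Dict[str, Any], index: int) -> tuple:
    if not isinstance(d, dict):
        raise ModelError(f"program #{index}: entry must be an object")
    membrane = str(_require(d, "membrane", f"program #{index}"))
    name = str(d.get("name", f"program-{index}"))
    production = _require(d, "production", f"program {name!r}")
    repartition = _require(d, "repartition", f"program {name!r}")
    if not isinstance(repartition, list):
        raise ModelError(f"program {name!r}: 'repartition' must be a list")
    terms = []
    for term in repartition:
        if not (isinstance(term, (list, tuple)) and len(term) == 2):
            raise ModelError(
                f"program {name!r}: repartition terms must be "
                f"[coefficient, target] pairs, got {term!r}"
            )
        coeff, target = term
        try:
            coeff = float(coeff)
        except (TypeError, ValueError):
            raise ModelError(
                f"program {name!r}: non-numeric repartition coefficient {coeff!r}"
            )
        terms.append((coeff, str(target)))
    enzyme = d.get("enzyme")
    enzyme = None if enzyme is None else str(enzyme)
    comparison = str(d.get("comparison", "non-strict"))
    prog = Program(
        name=name,
        production=str(production),
        repartition=tuple(terms),
        enzyme=enzyme,
        comparison=comparison,
    )
    return membrane, prog


def _policy_from_dict(d: Dict[str, Any]) -> ExecutionPolicy:
    if not isinstance(d, dict):
        raise ModelError("'policy' must be an object")
    halt = d.get("halt_variable")
    return ExecutionPolicy(
        mode=str(d.get("mode", "staged")),
        consumption=str(d.get("consumption", "non-consuming")),
        max_steps=int(d.get("max_steps", 1000)),
        halt_variable=None if halt is None else str(halt),
        halt_threshold=float(d.get("halt_threshold", 1.0)),
        halt_on_fixed_point=bool(d.get("halt_on_fixed_point", False)),
    )


def _schedule_from_list(entries: Any) -> List[ScheduleEntry]:
    if not isinstance(entries, list):
        raise ModelError("'schedule' must be a list")
    out = []
    for i, e in enumerate(entries):
        if not isinstance(e, dict):
            raise ModelError(f"schedule entry #{i} must be an object")
        membranes = _require(e, "membranes", f"schedule entry #{i}")
        programs = e.get("programs")
        out.append(
            ScheduleEntry(
                membranes=tuple(str(m) for m in membranes),
                programs=None if programs is None else frozenset(map(str, programs)),
                label=e.get("label"),
            )
        )
    return out


def parse_document(text: str) -> ModelDocument:
    """Parse a full model document (system + optional policy/schedule)."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ModelError(f"model file is not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise ModelError("model document must be a JSON object")
    membranes = [_membrane_from_dict(m) for m in _require(doc, "membranes", "model")]
    by_label = {mb.label: mb for mb in membranes}
    for i, p in enumerate(doc.get("programs", [])):
        membrane_label, prog = _program_from_dict(p, i)
        if membrane_label not in by_label:
            raise ModelError(
                f"program {prog.name!r} placed in unknown membrane "
                f"{membrane_label!r}"
            )
        by_label[membrane_label].programs.append(prog)
    system = ENPSystem(membranes)
    policy = _policy_from_dict(doc["policy"]) if "policy" in doc else None
    schedule = _schedule_from_list(doc["schedule"]) if "schedule" in doc else None
    return ModelDocument(system=system, policy=policy, schedule=schedule)


def parse_model(text: str) -> ENPSystem:
    """Parse a model file into a validated :class:`ENPSystem`."""
    return parse_document(text).system


def write_model(
    system: ENPSystem,
    policy: Optional[ExecutionPolicy] = None,
    schedule: Optional[List[ScheduleEntry]] = None,
    indent: Optional[int] = 1,
) -> str:
    """Serialize a system (and optional policy/schedule) to model JSON."""
    doc: Dict[str, Any] = {
        "membranes": [
            {
                "label": mb.label,
                "parent": mb.parent,
                "variables": mb.variables,
                "enzymes": list(mb.enzymes),
            }
            for mb in system.membranes
        ],
        "programs": [
            {
                "membrane": mb.label,
                "name": p.name,
                "production": p.production.source,
                "enzyme": p.enzyme,
                "repartition": [[c, t] for c, t in p.repartition],
                "comparison": p.comparison,
            }
            for mb in system.membranes
            for p in mb.programs
        ],
    }
    if policy is not None:
        doc["policy"] = {
            "mode": policy.mode,
            "consumption": policy.consumption,
            "max_steps": policy.max_steps,
            "halt_variable": policy.halt_variable,
            "halt_threshold": policy.halt_threshold,
            "halt_on_fixed_point": policy.halt_on_fixed_point,
        }
    if schedule is not None:
        doc["schedule"] = [
            {
                "membranes": list(e.membranes),
                "programs": None if e.programs is None else sorted(e.programs),
                "label": e.label,
            }
            for e in schedule
        ]
    return json.dumps(doc, indent=indent)
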