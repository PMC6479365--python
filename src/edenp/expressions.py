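"""Production-function expressions.

A production function is an arithmetic expression over numerical
variables: sums, differences, products, non-negative integer powers and
``sqrt``.  Expressions are parsed once (into a compiled code object) and
evaluated against a plain ``{name: value}`` mapping.

Productions generated for image-sized systems can be extremely long
left-associative chains (the halting rule lists every ED variable with a
zero coefficient), which overflows CPython's default recursion limit
during parsing and byte-compilation.  ``_deep_recursion`` raises the
limit proportionally to the operator count around those two calls only.
"""

from __future__ import annotations

import ast
import math
import sys
from contextlib import contextmanager
from typing import Iterator, Mapping, Tuple

from .errors import EvaluationError, ExpressionError

__all__ = ["Expression"]

_ALLOWED_BINOPS = (ast.Add, ast.Sub, ast.Mult, ast.Pow)
_ALLOWED_UNARY = (ast.USub, ast.UAdd)

# bytecode evaluation is iterative; only parse/compile recurse
_RECURSION_CAP = 100_000


@contextmanager
def _deep_recursion(source: str) -> Iterator[None]:
    ops = sum(source.count(c) for c in "+-*(")
    needed = min(1000 + 5 * ops, _RECURSION_CAP)
    old = sys.getrecursionlimit()
    if needed > old:
        sys.setrecursionlimit(needed)
    try:
        yield
    finally:
        sys.setrecursionlimit(old)


def _validate(tree: ast.Expression, source: str) -> Tuple[str, ...]:
    """Whitelist-check every node; return operand names in first-appearance
    order (iterative DFS so the order is deterministic and source-like)."""
    operands: list[str] = []
    seen: set[str] = set()
    stack: list[ast.AST] = [tree.body]
    while stack:
        node = stack.pop()
        if isinstance(node, ast.Constant):
            if not isinstance(node.value, (int, float)) or isinstance(node.value, bool):
                raise ExpressionError(f"non-numeric constant {node.value!r} in {source!r}")
        elif isinstance(node, ast.Name):
            if node.id not in seen:
                seen.add(node.id)
                operands.append(node.id)
        elif isinstance(node, ast.BinOp):
            if not isinstance(node.op, _ALLOWED_BINOPS):
                raise ExpressionError(
                    f"operator {type(node.op).__name__} not supported in {source!r}"
                )
            if isinstance(node.op, ast.Pow):
                exp = node.right
                if not (
                    isinstance(exp, ast.Constant)
                    and isinstance(exp.value, int)
                    and not isinstance(exp.value, bool)
                    and exp.value >= 0
                ):
                    raise ExpressionError(
                        f"exponent must be a non-negative integer constant in {source!r}"
                    )
                stack.append(node.left)
                continue
            stack.append(node.right)
            stack.append(node.left)
        elif isinstance(node, ast.UnaryOp):
            if not isinstance(node.op, _ALLOWED_UNARY):
                raise ExpressionError(
                    f"operator {type(node.op).__name__} not supported in {source!r}"
                )
            stack.append(node.operand)
        elif isinstance(node, ast.Call):
            if not (isinstance(node.func, ast.Name) and node.func.id == "sqrt"):
                raise ExpressionError(f"only sqrt() calls are allowed in {source!r}")
            if len(node.args) != 1 or node.keywords:
                raise ExpressionError(f"sqrt() takes exactly one argument in {source!r}")
            stack.append(node.args[0])
        else:
            raise ExpressionError(
                f"syntax element {type(node).__name__} not supported in {source!r}"
            )
    return tuple(operands)


class Expression:
    """A parsed, compiled production expression.

    Parameters
    ----------
    source:
        The expression text, e.g. ``"sqrt(gx*gx + gy*gy)"``.
    """

    __slots__ = ("source", "operands", "_code")

    def __init__(self, source: str):
        if not isinstance(source, str) or not source.strip():
            raise ExpressionError("production expression must be a non-empty string")
        self.source = source
        try:
            with _deep_recursion(source):
                tree = ast.parse(source, mode="eval")
                self.operands = _validate(tree, source)
                self._code = compile(tree, "<production>", "eval")
        except SyntaxError as exc:
            raise ExpressionError(f"cannot parse production {source!r}: {exc}") from exc
        except RecursionError as exc:
            raise ExpressionError(f"production {source!r} is too deeply nested") from exc

    def evaluate(self, values: Mapping[str, float]) -> float:
        """Evaluate against ``values``; pure, no state change."""
        try:
            result = eval(  # noqa: S307 - node whitelist enforced at parse time
                self._code, {"__builtins__": {}, "sqrt": math.sqrt}, values
            )
        except NameError as exc:
            raise EvaluationError(
                f"unresolved variable in production {self.source!r}: {exc}"
            ) from exc
        except ValueError as exc:
            raise EvaluationError(
                f"numerical error in production {self.source!r}: {exc}"
            ) from exc
        return float(result)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Expression) and self.source == other.source

    def __hash__(self) -> int:
        return hash(self.source)

    def __repr__(self) -> str:
        return f"Expression({self.source!r})"
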