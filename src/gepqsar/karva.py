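"""Karva-notation genotypes and their expression-tree phenotypes.

In gene expression programming a candidate model is stored as a
fixed-length linear string of symbols (the chromosome) split into a *head*,
which may hold function or terminal tokens, and a *tail* of terminals only.
With head length ``h`` and maximum function arity ``n``, a tail of length

    t = h * (n - 1) + 1

guarantees that level-order (breadth-first) decoding of the string always
yields a complete, finite expression tree regardless of what the head
contains.  The decoded tree is the phenotype: an ordinary arithmetic
expression over named descriptor variables.

Evaluation uses protected arithmetic -- division by zero, logarithms of
non-positive arguments, square roots of negatives, exponential overflow and
modulo by zero all map to defined finite values -- so every genotype
evaluates to a finite number on every finite input, and the evolutionary
search never has to discard an individual for a numerical accident.
"""

from __future__ import annotations

import json
import math
from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "KarvaError",
    "FunctionSymbol",
    "FunctionSet",
    "Chromosome",
    "Node",
    "ExpressionTree",
    "tail_length",
    "validate_chromosome",
    "decode",
    "random_chromosome",
    "arithmetic_set",
    "extended_set",
    "function_set_from_spec",
]

# bound on any intermediate value; keeps products/sums finite in float64
_BIG = 1e300
_EXP_CLAMP = 700.0
_TAN_CLAMP = 1e6


class KarvaError(ValueError):
    """Invalid chromosome, unknown token, or schema mismatch."""


def _finite(v):
    """Clamp an evaluation result into a finite float64 range (NaN -> 0)."""
    return np.clip(np.nan_to_num(v, nan=0.0, posinf=_BIG, neginf=-_BIG), -_BIG, _BIG)


# ---------------------------------------------------------------------------
# protected primitives (vectorised; work on scalars and arrays alike)

def p_add(a, b):
    return a + b


def p_sub(a, b):
    return a - b


def p_mul(a, b):
    return a * b


def p_div(a, b):
    """Protected division: x / 0 -> 1."""
    b = np.asarray(b, dtype=float)
    zero = b == 0
    return np.where(zero, 1.0, np.asarray(a, dtype=float) / np.where(zero, 1.0, b))


def p_sqrt(a):
    """Protected square root: negative arguments use their magnitude."""
    return np.sqrt(np.abs(a))


def p_log(a):
    """Protected natural log: log(y) = 0 for y <= 0."""
    a = np.asarray(a, dtype=float)
    pos = a > 0
    return np.where(pos, np.log(np.where(pos, a, 1.0)), 0.0)


def p_exp(a):
    """Exponential with the exponent clamped to +-700 (float64 safe)."""
    return np.exp(np.clip(a, -_EXP_CLAMP, _EXP_CLAMP))


def p_mod(a, b):
    """Protected floating remainder: mod(a, 0) -> 0."""
    b = np.asarray(b, dtype=float)
    zero = b == 0
    return np.where(zero, 0.0, np.fmod(np.asarray(a, dtype=float), np.where(zero, 1.0, b)))


def p_sin(a):
    return np.sin(a)


def p_tan(a):
    """Tangent clamped to +-1e6 so values near the singularities stay usable."""
    return np.clip(np.tan(a), -_TAN_CLAMP, _TAN_CLAMP)


@dataclass(frozen=True)
class FunctionSymbol:
    """A named arithmetic operation usable in chromosome heads."""

    token: str
    arity: int
    fn: Callable[..., np.ndarray] = field(compare=False, repr=False)

    def __post_init__(self):
        if self.arity < 1:
            raise KarvaError(f"function {self.token!r}: arity must be >= 1")


_INFIX = {"+", "-", "*", "/"}

_PRIMITIVES = {
    "+": FunctionSymbol("+", 2, p_add),
    "-": FunctionSymbol("-", 2, p_sub),
    "*": FunctionSymbol("*", 2, p_mul),
    "/": FunctionSymbol("/", 2, p_div),
    "q": FunctionSymbol("q", 1, p_sqrt),
    "mod": FunctionSymbol("mod", 2, p_mod),
    "exp": FunctionSymbol("exp", 1, p_exp),
    "log": FunctionSymbol("log", 1, p_log),
    "sin": FunctionSymbol("sin", 1, p_sin),
    "tan": FunctionSymbol("tan", 1, p_tan),
}


def _is_number(tok: str) -> bool:
    try:
        float(tok)
    except ValueError:
        return False
    return True


@dataclass(frozen=True)
class FunctionSet:
    """Alphabet of a chromosome: functions, variable terminals, constants.

    Tokens are case-insensitive and stored lowercase.  Numeric constant
    terminals are supported but separate from variables, so they can be
    switched off (the default for model evolution).
    """

    functions: tuple[FunctionSymbol, ...]
    terminals: tuple[str, ...]
    constants: tuple[str, ...] = ()
    name: str = "custom"

    def __post_init__(self):
        object.__setattr__(self, "terminals", tuple(t.lower() for t in self.terminals))
        object.__setattr__(self, "constants", tuple(self.constants))
        if not self.terminals:
            raise KarvaError("terminal set must be nonempty")
        ftok = [f.token for f in self.functions]
        if len(set(ftok)) != len(ftok):
            raise KarvaError("duplicate function tokens")
        overlap = set(ftok) & set(self.terminal_pool)
        if overlap:
            raise KarvaError(f"tokens used as both function and terminal: {sorted(overlap)}")
        for c in self.constants:
            if not _is_number(c):
                raise KarvaError(f"constant terminal {c!r} is not numeric")

    @property
    def max_arity(self) -> int:
        return max((f.arity for f in self.functions), default=1)

    @property
    def terminal_pool(self) -> tuple[str, ...]:
        return self.terminals + self.constants

    @property
    def head_pool(self) -> tuple[str, ...]:
        return tuple(f.token for f in self.functions) + self.terminal_pool

    def lookup(self, token: str) -> FunctionSymbol | None:
        for f in self.functions:
            if f.token == token:
                return f
        return None

    def is_known(self, token: str) -> bool:
        return self.lookup(token) is not None or token in self.terminal_pool

    def spec(self) -> dict:
        return {
            "name": self.name,
            "terminals": list(self.terminals),
            "constants": list(self.constants),
        }


def arithmetic_set(terminals: Sequence[str], constants: Sequence[str] = ()) -> FunctionSet:
    """The common function set {+, -, *, /, Q} (Q = square root)."""
    toks = ("+", "-", "*", "/", "q")
    return FunctionSet(tuple(_PRIMITIVES[t] for t in toks), tuple(terminals),
                       tuple(constants), name="arithmetic")


def extended_set(terminals: Sequence[str], constants: Sequence[str] = ()) -> FunctionSet:
    """The richer set {+, -, *, /, mod, exp, log, sin, tan} used for the
    published carcinogenicity rule."""
    toks = ("+", "-", "*", "/", "mod", "exp", "log", "sin", "tan")
    return FunctionSet(tuple(_PRIMITIVES[t] for t in toks), tuple(terminals),
                       tuple(constants), name="extended")


_SET_BUILDERS = {"arithmetic": arithmetic_set, "extended": extended_set}


def function_set_from_spec(spec: Mapping) -> FunctionSet:
    """Rebuild a named function set from its serialized description."""
    name = spec["name"]
    if name not in _SET_BUILDERS:
        raise KarvaError(f"unknown function set {name!r}")
    return _SET_BUILDERS[name](spec["terminals"], spec.get("constants", ()))


# ---------------------------------------------------------------------------
# chromosomes

def tail_length(head_length: int, max_arity: int) -> int:
    """Tail length t = h(n-1) + 1 for head length h and maximum arity n."""
    if head_length < 1 or max_arity < 1:
        raise KarvaError("head_length and max_arity must be positive")
    return head_length * (max_arity - 1) + 1


@dataclass(frozen=True)
class Chromosome:
    """Fixed-length Karva genotype: head of h symbols, tail of t terminals."""

    head_length: int
    symbols: tuple[str, ...]
    function_set: FunctionSet

    def __post_init__(self):
        object.__setattr__(self, "symbols", tuple(s.lower() for s in self.symbols))

    @property
    def tail_len(self) -> int:
        return tail_length(self.head_length, self.function_set.max_arity)

    @property
    def expected_length(self) -> int:
        return self.head_length + self.tail_len

    def validate(self) -> list[str]:
        return validate_chromosome(self)

    @property
    def is_valid(self) -> bool:
        return not self.validate()

    def to_token_string(self) -> str:
        return " ".join(self.symbols)

    def to_json(self) -> dict:
        return {
            "head_length": self.head_length,
            "symbols": list(self.symbols),
            "function_set": self.function_set.spec(),
        }

    @classmethod
    def from_json(cls, obj: Mapping) -> "Chromosome":
        fset = function_set_from_spec(obj["function_set"])
        return cls(int(obj["head_length"]), tuple(obj["symbols"]), fset)

    @classmethod
    def from_token_string(cls, s: str, head_length: int, function_set: FunctionSet) -> "Chromosome":
        return cls(head_length, tuple(s.split()), function_set)


def validate_chromosome(c: Chromosome) -> list[str]:
    """Report every structural violation of a chromosome; empty iff valid."""
    report: list[str] = []
    if len(c.symbols) != c.expected_length:
        report.append(
            f"length mismatch: got {len(c.symbols)}, expected "
            f"{c.expected_length} (head {c.head_length} + tail {c.tail_len})"
        )
    fset = c.function_set
    for i, tok in enumerate(c.symbols):
        if not fset.is_known(tok):
            report.append(f"unknown token {tok!r} at position {i}")
        elif i >= c.head_length and fset.lookup(tok) is not None:
            report.append(f"function in tail: {tok!r} at position {i}")
    return report


def random_chromosome(function_set: FunctionSet, head_length: int, rng: np.random.Generator) -> Chromosome:
    """Draw a uniformly random valid chromosome."""
    head_pool = function_set.head_pool
    tail_pool = function_set.terminal_pool
    t = tail_length(head_length, function_set.max_arity)
    head = [head_pool[rng.integers(len(head_pool))] for _ in range(head_length)]
    tail = [tail_pool[rng.integers(len(tail_pool))] for _ in range(t)]
    return Chromosome(head_length, tuple(head + tail), function_set)


# ---------------------------------------------------------------------------
# expression trees

@dataclass
class Node:
    token: str
    symbol: FunctionSymbol | None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return self.symbol is None


@dataclass
class ExpressionTree:
    """Decoded phenotype: a finite arithmetic tree over named variables."""

    root: Node

    def variables(self) -> set[str]:
        out: set[str] = set()
        stack = [self.root]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                if not _is_number(n.token):
                    out.add(n.token)
            else:
                stack.extend(n.children)
        return out

    def size(self) -> int:
        count, stack = 0, [self.root]
        while stack:
            n = stack.pop()
            count += 1
            stack.extend(n.children)
        return count

    def to_infix(self) -> str:
        return _infix(self.root)

    def evaluate(self, env: Mapping[str, float] | Mapping[str, np.ndarray]):
        """Evaluate over scalars or aligned numpy arrays.

        Unknown variables raise :class:`KarvaError`; the result is always
        finite for finite inputs.
        """
        lowered = {k.lower(): np.asarray(v, dtype=float) for k, v in env.items()}
        out = _eval(self.root, lowered)
        arr = np.asarray(out, dtype=float)
        if arr.ndim == 0:
            return float(arr)
        return arr

    def __call__(self, env):
        return self.evaluate(env)


def _infix(node: Node) -> str:
    if node.is_leaf:
        return node.token
    if node.token in _INFIX:
        left, right = (_infix(ch) for ch in node.children)
        return f"({left}{node.token}{right})"
    args = ",".join(_infix(ch) for ch in node.children)
    return f"{node.token}({args})"


def _eval(node: Node, env: Mapping[str, np.ndarray]):
    if node.is_leaf:
        tok = node.token
        if tok in env:
            return env[tok]
        if _is_number(tok):
            return float(tok)
        raise KarvaError(f"unknown variable {tok!r} in expression")
    args = [_eval(ch, env) for ch in node.children]
    return _finite(node.symbol.fn(*args))


def decode(c: Chromosome) -> ExpressionTree:
    """Level-order Karva decoding of a valid chromosome.

    The first symbol is the root; each subsequent tree level is filled
    left-to-right, consuming one token per open child slot.  Decoding stops
    when no slots remain open; trailing unused tokens are ignored.
    """
    problems = validate_chromosome(c)
    if problems:
        raise KarvaError("invalid chromosome: " + "; ".join(problems))
    fset = c.function_set
    toks = c.symbols
    root = Node(toks[0], fset.lookup(toks[0]))
    queue: deque[Node] = deque([root])
    i = 1
    while queue:
        node = queue.popleft()
        if node.symbol is None:
            continue
        for _ in range(node.symbol.arity):
            child = Node(toks[i], fset.lookup(toks[i]))
            i += 1
            node.children.append(child)
            queue.append(child)
    return ExpressionTree(root)
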