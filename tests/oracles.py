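"""Independent reference implementations used only to cross-check the
package.  Each oracle is written directly from the intended semantics,
deliberately sharing no code with the modules it checks."""

from __future__ import annotations

import random

# ---------------------------------------------------------------------------
# expression oracle: tuple-based AST, renderer and brute-force evaluator

_CMP_OPS = ["==", "!=", "<", "<=", ">", ">="]
_NAMES = ["a", "b", "mood", "random_choice", "x1", "long_name"]
_WORDS = ["apple", "banana", "x", "myValue", "3", "10", "0"]


def gen_expr(rng: random.Random, depth: int = 3):
    """Random boolean expression as a tuple AST."""
    roll = rng.random()
    if depth <= 0 or roll < 0.45:
        return ("cmp", rng.choice(_CMP_OPS), gen_operand(rng), gen_operand(rng))
    if roll < 0.6:
        return ("not", gen_expr(rng, depth - 1))
    if roll < 0.8:
        return ("and", [gen_expr(rng, depth - 1)
                        for _ in range(rng.randint(2, 3))])
    if roll < 0.95:
        return ("or", [gen_expr(rng, depth - 1)
                       for _ in range(rng.randint(2, 3))])
    return gen_operand(rng)  # bare truthiness test


def gen_operand(rng: random.Random):
    roll = rng.random()
    if roll < 0.45:
        return ("var", rng.choice(_NAMES))
    if roll < 0.75:
        number = rng.choice([0, 1, 2, 3, 10, -1, 2.5])
        return ("lit", float(number))
    return ("lit", rng.choice(_WORDS))


def render(node) -> str:
    """Expression text with explicit parentheses around logical operands."""
    kind = node[0]
    if kind == "lit":
        value = node[1]
        if isinstance(value, float):
            return str(int(value)) if value.is_integer() else repr(value)
        return f"'{value}'"
    if kind == "var":
        return node[1]
    if kind == "cmp":
        return f"{render(node[2])}{node[1]}{render(node[3])}"
    if kind == "not":
        return f"!({render(node[1])})"
    joiner = "&&" if kind == "and" else "||"
    return joiner.join(f"({render(child)})" for child in node[1])


def _number(value):
    try:
        return float(str(value))
    except (TypeError, ValueError):
        return None


def ref_eval(node, store: dict) -> bool:
    """Brute-force evaluator: numeric comparison when both sides are
    numeric, lexicographic otherwise; any missing variable makes the
    enclosing comparison (or bare test) false."""
    kind = node[0]
    if kind == "cmp":
        op, lhs, rhs = node[1], node[2], node[3]
        sides = []
        for side in (lhs, rhs):
            if side[0] == "var":
                if side[1] not in store:
                    return False
                sides.append(store[side[1]])
            else:
                sides.append(side[1])
        left, right = sides
        ln, rn = _number(left), _number(right)
        if ln is not None and rn is not None:
            left, right = ln, rn
        else:
            left, right = str(left), str(right)
        return {"==": left == right, "!=": left != right,
                "<": left < right, "<=": left <= right,
                ">": left > right, ">=": left >= right}[op]
    if kind == "not":
        return not ref_eval(node[1], store)
    if kind == "and":
        return all(ref_eval(child, store) for child in node[1])
    if kind == "or":
        return any(ref_eval(child, store) for child in node[1])
    if kind == "var":
        if node[1] not in store:
            return False
        return str(store[node[1]]).strip().lower() not in ("", "0", "false")
    return str(node[1]).strip().lower() not in ("", "0", "false")


def gen_store(rng: random.Random) -> dict:
    store = {}
    for name in _NAMES:
        if rng.random() < 0.7:
            store[name] = rng.choice(["apple", "myValue", "3", "10", 2, 0, "x", ""])
    return store


# ---------------------------------------------------------------------------
# dataflow oracle: exhaustive write-before-read path enumeration
#
# A small protocol is modelled as a nested list of steps:
#   ("write", name)            - a widget that stores a value
#   ("read", name)             - a test or placeholder that reads a value
#   ("choose", [branch, ...], has_otherwise)  - exactly one branch runs
#                                (or none, when no otherwise exists)
# The oracle enumerates every branch combination and reports whether some
# path performs a read before any write of that name.


def enumerate_paths(steps):
    """All flattened (op, name) sequences the protocol can execute."""
    paths = [[]]
    for step in steps:
        if step[0] in ("write", "read"):
            paths = [p + [step] for p in paths]
        else:
            _, branches, has_otherwise = step
            expanded = []
            for path in paths:
                taken = list(branches)
                if not has_otherwise:
                    taken.append([])  # the nothing-selected path
                for branch in taken:
                    for tail in enumerate_paths(branch):
                        expanded.append(path + tail)
            paths = expanded
    return paths


def has_dangling_read(steps) -> bool:
    """True when some executable path reads a name never written before
    that point on the same path."""
    for path in enumerate_paths(steps):
        written = set()
        for op, name in path:
            if op == "write":
                written.add(name)
            elif name not in written:
                return True
    return False
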