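"""Truth tables, product terms and sum-of-products covers.

The central representation is the :class:`TruthTable`: a complete
specification of one or more Boolean outputs over ``N`` named inputs,
stored as on-sets of minterm indices.  Bit ``k`` (least significant) of a
minterm index corresponds to ``input_names[k]``; in PLA text the leftmost
input column is input 0.

Product terms (:class:`Implicant`) map input indices to a required
polarity; inputs absent from the mapping are unconstrained.  A
:class:`Cover` is an ordered list of implicants whose OR realises a
function; the empty cover is the constant-0 function.
"""

from __future__ import annotations

import enum
import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence


class Polarity(enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


class PLAParseError(ValueError):
    """Malformed PLA text; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ExpressionError(ValueError):
    """Syntax error or unknown identifier in a Boolean expression."""


@dataclass(frozen=True)
class Implicant:
    """A product term: conjunction of literals over a subset of the inputs.

    Stored as a sorted tuple of ``(input_index, Polarity)`` pairs so the
    object is hashable; :attr:`literals` exposes the mapping view.  An
    empty tuple is the tautology term (constant 1).
    """

    terms: tuple[tuple[int, Polarity], ...] = ()

    def __post_init__(self):
        indices = [i for i, _ in self.terms]
        if len(set(indices)) != len(indices):
            raise ValueError("duplicate input index in implicant")
        if any(i < 0 for i in indices):
            raise ValueError("negative input index")
        object.__setattr__(self, "terms", tuple(sorted(self.terms)))

    @classmethod
    def from_literals(cls, literals: Mapping[int, Polarity]) -> "Implicant":
        return cls(tuple(sorted(literals.items())))

    @classmethod
    def from_value_mask(cls, value: int, mask: int, n: int) -> "Implicant":
        lits = {}
        for k in range(n):
            if mask >> k & 1:
                lits[k] = Polarity.POSITIVE if value >> k & 1 else Polarity.NEGATIVE
        return cls.from_literals(lits)

    @property
    def literals(self) -> dict[int, Polarity]:
        return dict(self.terms)

    @property
    def n_literals(self) -> int:
        return len(self.terms)

    def value_mask(self) -> tuple[int, int]:
        value = mask = 0
        for k, pol in self.terms:
            mask |= 1 << k
            if pol is Polarity.POSITIVE:
                value |= 1 << k
        return value, mask

    def evaluate(self, assignment: Sequence[int]) -> int:
        for k, pol in self.terms:
            if k >= len(assignment):
                raise ValueError(f"assignment too short for input index {k}")
            bit = int(bool(assignment[k]))
            if (pol is Polarity.POSITIVE) != bool(bit):
                return 0
        return 1

    def minterms(self, n: int) -> frozenset[int]:
        """All minterm indices of an N-input space covered by this term."""
        value, mask = self.value_mask()
        free = [k for k in range(n) if not mask >> k & 1]
        out = set()
        for bits in itertools.product((0, 1), repeat=len(free)):
            m = value
            for k, b in zip(free, bits):
                m |= b << k
            out.add(m)
        return frozenset(out)

    def sort_key(self) -> tuple:
        value, mask = self.value_mask()
        return (len(self.terms), mask, value)


@dataclass(frozen=True)
class Cover:
    """Sum-of-products: OR over :class:`Implicant` terms."""

    terms: tuple[Implicant, ...]
    n_inputs: int

    def __post_init__(self):
        object.__setattr__(self, "terms", tuple(self.terms))
        for t in self.terms:
            if any(k >= self.n_inputs for k, _ in t.terms):
                raise ValueError("implicant references input beyond n_inputs")

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def n_literals(self) -> int:
        return sum(t.n_literals for t in self.terms)

    def on_set(self) -> frozenset[int]:
        out: set[int] = set()
        for t in self.terms:
            out |= t.minterms(self.n_inputs)
        return frozenset(out)


def evaluate_cover(cover: Cover, assignment: Sequence[int]) -> int:
    """OR over terms of AND over literals; empty cover is constant 0."""
    if len(assignment) != cover.n_inputs:
        raise ValueError(
            f"assignment length {len(assignment)} != n_inputs {cover.n_inputs}"
        )
    return int(any(t.evaluate(assignment) for t in cover.terms))


@dataclass(frozen=True)
class TruthTable:
    """Complete multi-output Boolean function over named inputs."""

    input_names: tuple[str, ...]
    output_names: tuple[str, ...]
    on_sets: Mapping[str, frozenset[int]]

    def __post_init__(self):
        object.__setattr__(self, "input_names", tuple(self.input_names))
        object.__setattr__(self, "output_names", tuple(self.output_names))
        if len(set(self.input_names)) != len(self.input_names):
            raise ValueError("duplicate input names")
        if len(set(self.output_names)) != len(self.output_names):
            raise ValueError("duplicate output names")
        if not self.input_names:
            raise ValueError("need at least one input")
        if not self.output_names:
            raise ValueError("need at least one output")
        n = len(self.input_names)
        clean = {}
        for name in self.output_names:
            if name not in self.on_sets:
                raise ValueError(f"missing on-set for output {name!r}")
            ms = frozenset(int(m) for m in self.on_sets[name])
            if any(m < 0 or m >= 1 << n for m in ms):
                raise ValueError(f"minterm out of range for output {name!r}")
            clean[name] = ms
        object.__setattr__(self, "on_sets", clean)

    @property
    def n_inputs(self) -> int:
        return len(self.input_names)

    def on_set(self, output: str | None = None) -> frozenset[int]:
        if output is None:
            if len(self.output_names) != 1:
                raise ValueError("output label required for multi-output table")
            output = self.output_names[0]
        if output not in self.on_sets:
            raise KeyError(f"unknown output {output!r}")
        return self.on_sets[output]

    def evaluate(self, assignment: Sequence[int], output: str | None = None) -> int:
        if len(assignment) != self.n_inputs:
            raise ValueError("assignment length mismatch")
        idx = sum(int(bool(b)) << k for k, b in enumerate(assignment))
        return int(idx in self.on_set(output))

    def assignment_of(self, minterm: int) -> tuple[int, ...]:
        return tuple(minterm >> k & 1 for k in range(self.n_inputs))


def canonical_minterms(tt: TruthTable, output: str | None = None) -> Cover:
    """Canonical sum of minterms: one full-literal implicant per on minterm."""
    n = tt.n_inputs
    full = (1 << n) - 1
    terms = [
        Implicant.from_value_mask(m, full, n) for m in sorted(tt.on_set(output))
    ]
    return Cover(tuple(terms), n)


# ---------------------------------------------------------------------------
# PLA text format (Berkeley subset: .i/.o/.ilb/.ob/.p/.e, cubes 0/1/-, fd type)
# ---------------------------------------------------------------------------

def parse_pla(text: str) -> TruthTable:
    """Parse a PLA-dialect string into a fully expanded :class:`TruthTable`.

    ``-`` in the input cube expands to both values; output characters are
    ``1`` (on), ``0``/``~`` (off / unspecified, both default to 0).  Rows
    assigning contradictory explicit values to the same minterm raise
    :class:`PLAParseError` with the line number.
    """
    n_in = n_out = None
    ilb: list[str] | None = None
    ob: list[str] | None = None
    # explicit[output][minterm] = (bit, line) for contradiction detection
    explicit: list[dict[int, tuple[int, int]]] = []
    rows_seen = False

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("."):
            parts = line.split()
            key = parts[0]
            if key == ".i":
                if len(parts) != 2 or not parts[1].isdigit():
                    raise PLAParseError("malformed .i directive", lineno)
                n_in = int(parts[1])
                if n_in < 1:
                    raise PLAParseError(".i must be >= 1", lineno)
            elif key == ".o":
                if len(parts) != 2 or not parts[1].isdigit():
                    raise PLAParseError("malformed .o directive", lineno)
                n_out = int(parts[1])
                if n_out < 1:
                    raise PLAParseError(".o must be >= 1", lineno)
                explicit = [dict() for _ in range(n_out)]
            elif key == ".ilb":
                ilb = parts[1:]
            elif key == ".ob":
                ob = parts[1:]
            elif key in (".p", ".type"):
                pass  # row count / fd type: informative only
            elif key == ".e" or key == ".end":
                break
            else:
                raise PLAParseError(f"unknown directive {key}", lineno)
            continue
        # cube row
        if n_in is None or n_out is None:
            raise PLAParseError("cube row before .i/.o header", lineno)
        fields = line.split()
        if len(fields) == 2:
            in_cube, out_cube = fields
        elif len(fields) == 1 and len(line) == n_in + n_out:
            in_cube, out_cube = line[:n_in], line[n_in:]
        else:
            raise PLAParseError("cube row must have input and output parts", lineno)
        if len(in_cube) != n_in:
            raise PLAParseError(
                f"input cube width {len(in_cube)} != .i {n_in}", lineno
            )
        if len(out_cube) != n_out:
            raise PLAParseError(
                f"output width {len(out_cube)} != .o {n_out}", lineno
            )
        if any(c not in "01-" for c in in_cube):
            raise PLAParseError(f"bad input cube {in_cube!r}", lineno)
        if any(c not in "01~" for c in out_cube):
            raise PLAParseError(f"bad output part {out_cube!r}", lineno)
        rows_seen = True
        free = [k for k, c in enumerate(in_cube) if c == "-"]
        base = sum(1 << k for k, c in enumerate(in_cube) if c == "1")
        for bits in itertools.product((0, 1), repeat=len(free)):
            m = base
            for k, b in zip(free, bits):
                m |= b << k
            for j, c in enumerate(out_cube):
                if c == "~":
                    continue
                bit = int(c)
                prev = explicit[j].get(m)
                if prev is not None and prev[0] != bit:
                    raise PLAParseError(
                        f"contradictory value for minterm {m}, output {j} "
                        f"(previously set on line {prev[1]})",
                        lineno,
                    )
                explicit[j][m] = (bit, lineno)

    if n_in is None or n_out is None:
        raise PLAParseError("missing .i/.o header")
    del rows_seen
    input_names = tuple(ilb) if ilb else tuple(f"x{k}" for k in range(n_in))
    output_names = tuple(ob) if ob else tuple(f"f{j}" for j in range(n_out))
    if len(input_names) != n_in:
        raise PLAParseError(".ilb name count does not match .i")
    if len(output_names) != n_out:
        raise PLAParseError(".ob name count does not match .o")
    on_sets = {
        output_names[j]: frozenset(
            m for m, (bit, _) in explicit[j].items() if bit == 1
        )
        for j in range(n_out)
    }
    return TruthTable(input_names, output_names, on_sets)


def write_pla(tt: TruthTable) -> str:
    """Serialize a table to PLA text; round-trips through :func:`parse_pla`."""
    n = tt.n_inputs
    lines = [
        f".i {n}",
        f".o {len(tt.output_names)}",
        ".ilb " + " ".join(tt.input_names),
        ".ob " + " ".join(tt.output_names),
    ]
    rows = []
    care = sorted(set().union(*(tt.on_sets[o] for o in tt.output_names)) or set())
    for m in care:
        cube = "".join("1" if m >> k & 1 else "0" for k in range(n))
        outs = "".join(
            "1" if m in tt.on_sets[o] else "0" for o in tt.output_names
        )
        rows.append(f"{cube} {outs}")
    lines.append(f".p {len(rows)}")
    lines.extend(rows)
    lines.append(".e")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Boolean expression grammar: NOT/!/¬ > AND/&/· > OR/+/|, parentheses
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<lparen>\()|(?P<rparen>\))|(?P<not>!|¬|\bNOT\b)"
    r"|(?P<and>&|·|\*|\bAND\b)|(?P<or>\||\+|\bOR\b)"
    r"|(?P<ident>[A-Za-zα-ω_][A-Za-z0-9α-ω_]*))",
    re.IGNORECASE,
)


def _tokenize(expr: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(expr):
        m = _TOKEN_RE.match(expr, pos)
        if m is None or m.end() == pos:
            if expr[pos:].strip():
                raise ExpressionError(
                    f"syntax error at position {pos}: {expr[pos:pos + 10]!r}"
                )
            break
        kind = m.lastgroup
        tokens.append((kind, m.group(kind), m.start(kind)))
        pos = m.end()
    return tokens


class _ExprParser:
    def __init__(self, tokens, names):
        self.tokens = tokens
        self.pos = 0
        self.names = {name: k for k, name in enumerate(names)}

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        if tok is None:
            raise ExpressionError("unexpected end of expression")
        self.pos += 1
        return tok

    def parse(self):
        node = self.parse_or()
        if self.peek() is not None:
            kind, text, at = self.peek()
            raise ExpressionError(f"unexpected {text!r} at position {at}")
        return node

    def parse_or(self):
        node = self.parse_and()
        while self.peek() and self.peek()[0] == "or":
            self.next()
            rhs = self.parse_and()
            node = ("or", node, rhs)
        return node

    def parse_and(self):
        node = self.parse_factor()
        while self.peek() and self.peek()[0] == "and":
            self.next()
            rhs = self.parse_factor()
            node = ("and", node, rhs)
        return node

    def parse_factor(self):
        kind, text, at = self.next()
        if kind == "not":
            return ("not", self.parse_factor())
        if kind == "lparen":
            node = self.parse_or()
            tok = self.peek()
            if tok is None or tok[0] != "rparen":
                raise ExpressionError(f"unclosed parenthesis opened at {at}")
            self.next()
            return node
        if kind == "ident":
            if text not in self.names:
                raise ExpressionError(f"unknown identifier {text!r} at position {at}")
            return ("var", self.names[text])
        raise ExpressionError(f"unexpected {text!r} at position {at}")


def _eval_node(node, assignment) -> int:
    op = node[0]
    if op == "var":
        return assignment[node[1]]
    if op == "not":
        return 1 - _eval_node(node[1], assignment)
    if op == "and":
        return _eval_node(node[1], assignment) & _eval_node(node[2], assignment)
    return _eval_node(node[1], assignment) | _eval_node(node[2], assignment)


def parse_expression(
    expr: str, input_names: Sequence[str], output_name: str = "f"
) -> TruthTable:
    """Build a truth table from a Boolean expression by exhaustive evaluation.

    Grammar: ``NOT``/``!``/``¬``, ``AND``/``&``/``·``, ``OR``/``+``/``|``,
    parentheses; precedence NOT > AND > OR.
    """
    names = tuple(input_names)
    node = _ExprParser(_tokenize(expr), names).parse()
    n = len(names)
    on = set()
    for m in range(1 << n):
        assignment = tuple(m >> k & 1 for k in range(n))
        if _eval_node(node, assignment):
            on.add(m)
    return TruthTable(names, (output_name,), {output_name: frozenset(on)})


# ---------------------------------------------------------------------------
# Built-in example functions
# ---------------------------------------------------------------------------

_PARITY_RE = re.compile(r"^parity(\d+)$")


def builtin_function(name: str) -> TruthTable:
    """Named example functions with their conventional stimulus labels.

    ``majority3``: 1 iff at least two of (DEX, EST, PRO) are present.
    ``comparator2bit``: compares A = (a1, a0) = (EST, DOX) against
    B = (b1, b0) = (PRO, DEX); outputs ``A_gt_B`` and ``A_lt_B`` (equality
    leaves both low — no signal).
    ``mux4to1``: selectors (S0, S1) = (PRO, DOX) route one of the data
    inputs (I0..I3) = (ALD, aCa, EST, DEX) to the output.
    ``parityK``: odd parity over K generic inputs.
    """
    if name == "majority3":
        names = ("DEX", "EST", "PRO")
        on = frozenset(
            m for m in range(8) if bin(m).count("1") >= 2
        )
        return TruthTable(names, ("f",), {"f": on})
    if name == "comparator2bit":
        # bit order: (a1, a0, b1, b0) = (EST, DOX, PRO, DEX)
        names = ("EST", "DOX", "PRO", "DEX")
        gt, lt = set(), set()
        for m in range(16):
            a1, a0, b1, b0 = (m >> k & 1 for k in range(4))
            a, b = 2 * a1 + a0, 2 * b1 + b0
            if a > b:
                gt.add(m)
            elif a < b:
                lt.add(m)
        return TruthTable(
            names, ("A_gt_B", "A_lt_B"),
            {"A_gt_B": frozenset(gt), "A_lt_B": frozenset(lt)},
        )
    if name == "mux4to1":
        # bit order: (S0, S1, I0, I1, I2, I3) = (PRO, DOX, ALD, aCa, EST, DEX)
        names = ("PRO", "DOX", "ALD", "aCa", "EST", "DEX")
        on = set()
        for m in range(64):
            s0, s1 = m & 1, m >> 1 & 1
            sel = 2 * s1 + s0
            if m >> (2 + sel) & 1:
                on.add(m)
        return TruthTable(names, ("f",), {"f": frozenset(on)})
    if name == "and2":
        return TruthTable(("EST", "DEX"), ("f",), {"f": frozenset({3})})
    if name == "nor2":
        return TruthTable(("EST", "DEX"), ("f",), {"f": frozenset({0})})
    if name == "nimplies2":
        # a AND NOT b: the negated implication a -/-> b
        return TruthTable(("EST", "DEX"), ("f",), {"f": frozenset({1})})
    m = _PARITY_RE.match(name)
    if m:
        k = int(m.group(1))
        if k < 1:
            raise ValueError("parity needs at least 1 input")
        names = tuple(f"x{j}" for j in range(k))
        on = frozenset(v for v in range(1 << k) if bin(v).count("1") % 2 == 1)
        return TruthTable(names, ("f",), {"f": on})
    raise ValueError(f"unknown builtin function {name!r}")


BUILTIN_NAMES = (
    "majority3",
    "comparator2bit",
    "mux4to1",
    "and2",
    "nor2",
    "nimplies2",
)


def count_functions(n: int) -> int:
    """Number of distinct N-input single-output Boolean functions: 2^(2^N)."""
    if n < 0:
        raise ValueError("N must be non-negative")
    return 1 << (1 << n)


# ---------------------------------------------------------------------------
# CSV truth tables (header: input names then output names; row per assignment)
# ---------------------------------------------------------------------------

def read_csv_table(path_or_buf, n_inputs: int | None = None) -> TruthTable:
    """Read a truth table from CSV: input columns first, then output columns.

    Every one of the 2^N assignments must appear exactly once.
    """
    import pandas as pd

    df = pd.read_csv(path_or_buf)
    cols = list(df.columns)
    if n_inputs is None:
        # infer: smallest prefix whose assignment count matches the row count
        n_inputs = next(
            (k for k in range(1, len(cols)) if len(df) == 1 << k), None
        )
        if n_inputs is None:
            raise ValueError("cannot infer input count from row count")
    input_names = tuple(cols[:n_inputs])
    output_names = tuple(cols[n_inputs:])
    if not output_names:
        raise ValueError("no output columns")
    seen = set()
    on_sets: dict[str, set[int]] = {o: set() for o in output_names}
    for _, row in df.iterrows():
        m = sum(int(row[name]) << k for k, name in enumerate(input_names))
        if m in seen:
            raise ValueError(f"duplicate assignment row for minterm {m}")
        seen.add(m)
        for o in output_names:
            if int(row[o]):
                on_sets[o].add(m)
    if len(seen) != 1 << n_inputs:
        raise ValueError("incomplete truth table: missing assignments")
    return TruthTable(
        input_names, output_names, {o: frozenset(s) for o, s in on_sets.items()}
    )


def write_csv_table(tt: TruthTable) -> str:
    """Serialize to the CSV dialect accepted by :func:`read_csv_table`."""
    lines = [",".join(tt.input_names + tt.output_names)]
    for m in range(1 << tt.n_inputs):
        bits = [str(m >> k & 1) for k in range(tt.n_inputs)]
        outs = [str(int(m in tt.on_sets[o])) for o in tt.output_names]
        lines.append(",".join(bits + outs))
    return "\n".join(lines) + "\n"
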