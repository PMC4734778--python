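"""Compile Boolean functions into distributed multicellular consortium designs.

The transformation is the double-negation / De Morgan rewrite of a minimal
sum-of-products.  Each product term becomes one spatially isolated module
(consortium): every literal is inverted into a sensor cell specification —
a positive literal ``x`` becomes a NOT cell on ``x`` (secretes the wiring
molecule when ``x`` is absent) and a negated literal becomes an ID cell
(secretes when ``x`` is present).  The module's input-layer cells share one
wiring molecule (an implicit OR) which represses the output-layer cell, so
the module computes NOR over the inverted literals — exactly the original
AND term.  The circuit output is the OR over modules, read either as the
maximum reporter signal across chambers (transducer) or through an optional
saturating buffer cell pooling a secreted output.

Resource scaling of the architecture for N inputs: at most Z = 2N + 1 cell
types (an ID and a NOT sensor per input plus one output cell), at most
M = 2^(N-1) modules for any single-output function, while the number of
implementable functions grows as B = 2^(2^N).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .minimize import minimize_sop
from .truthtable import Cover, Implicant, Polarity, TruthTable


class Logic(enum.Enum):
    ID = "ID"
    NOT = "NOT"


@dataclass(frozen=True)
class ThetaTerm:
    """One input-layer cell slot: which input it senses and with which logic.

    The logic is the inversion of the source literal's polarity: positive
    literal -> NOT cell, negative literal -> ID cell.
    """

    input_index: int
    logic: Logic

    def __post_init__(self):
        if self.input_index < 0:
            raise ValueError("negative input index")

    def sort_key(self):
        return (self.input_index, self.logic.value)


@dataclass(frozen=True)
class ModuleSpec:
    """One consortium chamber: IL cells plus an output-layer cell.

    The chamber computes NOR over its IL cells' wire signals.  A module
    with zero IL cells is the tautology term: no wire is ever present and
    the OL cell fires constitutively.
    """

    il_cells: tuple[ThetaTerm, ...]
    output_label: str = "f"
    ol_cell: str = "OL_1"

    def __post_init__(self):
        cells = tuple(sorted(self.il_cells, key=ThetaTerm.sort_key))
        idx = [c.input_index for c in cells]
        if len(set(idx)) != len(idx):
            raise ValueError("at most one IL cell per input index in a module")
        object.__setattr__(self, "il_cells", cells)

    def evaluate(self, assignment: Sequence[int]) -> int:
        """Ideal Boolean NOR over the inverted-literal cells."""
        any_wire = False
        for cell in self.il_cells:
            x = int(bool(assignment[cell.input_index]))
            wire = x if cell.logic is Logic.ID else 1 - x
            any_wire = any_wire or bool(wire)
        return 0 if any_wire else 1


@dataclass(frozen=True)
class CircuitDesign:
    """A compiled consortium design: modules, inventory, buffer flag."""

    input_names: tuple[str, ...]
    modules: tuple[ModuleSpec, ...]
    output_names: tuple[str, ...]
    uses_buffer: bool = False

    def __post_init__(self):
        object.__setattr__(self, "input_names", tuple(self.input_names))
        object.__setattr__(self, "modules", tuple(self.modules))
        object.__setattr__(self, "output_names", tuple(self.output_names))
        for mod in self.modules:
            if mod.output_label not in self.output_names:
                raise ValueError(
                    f"module output {mod.output_label!r} not a declared output"
                )
            for cell in mod.il_cells:
                if cell.input_index >= len(self.input_names):
                    raise ValueError("IL cell references undeclared input")

    @property
    def n_inputs(self) -> int:
        return len(self.input_names)

    @property
    def m_design(self) -> int:
        return len(self.modules)

    def il_types(self) -> frozenset[tuple[int, Logic]]:
        return frozenset(
            (c.input_index, c.logic) for mod in self.modules for c in mod.il_cells
        )

    def ol_types(self) -> frozenset[str]:
        return frozenset(mod.ol_cell for mod in self.modules)

    def modules_for(self, output: str) -> tuple[ModuleSpec, ...]:
        return tuple(m for m in self.modules if m.output_label == output)

    def evaluate(self, assignment: Sequence[int], output: str | None = None) -> int:
        """Ideal Boolean semantics: OR over the output's NOR modules."""
        if output is None:
            if len(self.output_names) != 1:
                raise ValueError("output label required")
            output = self.output_names[0]
        return int(any(m.evaluate(assignment) for m in self.modules_for(output)))


@dataclass(frozen=True)
class ResourceSummary:
    """Architecture bounds at N inputs, plus counts for a concrete design."""

    n_inputs: int
    z_bound: int
    m_bound: int
    b_count: int
    il_types_used: int | None = None
    ol_types_used: int | None = None
    buf_types_used: int | None = None
    modules_used: int | None = None


def scaling_bounds(n: int) -> ResourceSummary:
    """Exact integer resource bounds for the N-input architecture.

    Library size Z = 2N + 1, worst-case single-output module count
    M = 2^(N-1), implementable function count B = 2^(2^N).
    """
    if n < 1:
        raise ValueError("N must be >= 1")
    return ResourceSummary(
        n_inputs=n,
        z_bound=2 * n + 1,
        m_bound=1 << (n - 1),
        b_count=1 << (1 << n),
    )


def ilf_transform(
    cover: Cover, output_label: str = "f", ol_cell: str = "OL_1"
) -> list[ModuleSpec]:
    """Inverted-logic rewrite: one NOR module per product term.

    Positive literal -> NOT cell; negative literal -> ID cell; unconstrained
    inputs produce no cell.  The module's NOR equals the term's AND on every
    assignment.
    """
    modules = []
    for term in cover.terms:
        cells = tuple(
            ThetaTerm(k, Logic.NOT if pol is Polarity.POSITIVE else Logic.ID)
            for k, pol in term.terms
        )
        modules.append(ModuleSpec(cells, output_label, ol_cell))
    return modules


@dataclass(frozen=True)
class CompileOptions:
    """Output-cell assignment and buffer usage for compilation.

    ``ol_cells``: pool of output-layer cell identifiers assigned to outputs
    in order; one distinct OL type per output.  ``use_buffer`` selects the
    secreted-output integration stage (an extra buffer chamber downstream).
    """

    ol_cells: tuple[str, ...] = ("OL_1", "OL_2")
    use_buffer: bool = False

    @classmethod
    def secreted(cls) -> "CompileOptions":
        return cls(ol_cells=("OL_3",), use_buffer=True)


def compile_circuit(
    tt: TruthTable, options: CompileOptions | None = None
) -> CircuitDesign:
    """Minimize each output and apply the inverted-logic transform.

    Outputs are compiled fully independently (no module sharing); each is
    assigned its own OL cell type from ``options.ol_cells``.
    """
    options = options or CompileOptions()
    if len(tt.output_names) > len(options.ol_cells):
        raise ValueError(
            f"{len(tt.output_names)} outputs but only "
            f"{len(options.ol_cells)} OL cell types available"
        )
    modules: list[ModuleSpec] = []
    for out, ol in zip(tt.output_names, options.ol_cells):
        cover = minimize_sop(tt, out)
        modules.extend(ilf_transform(cover, output_label=out, ol_cell=ol))
    return CircuitDesign(
        input_names=tt.input_names,
        modules=tuple(modules),
        output_names=tt.output_names,
        uses_buffer=options.use_buffer,
    )


def design_inventory(design: CircuitDesign) -> ResourceSummary:
    """Count distinct cell types and chambers used by a concrete design.

    The optional buffer adds one cell type and one chamber.
    """
    bounds = scaling_bounds(design.n_inputs)
    buf = 1 if design.uses_buffer else 0
    return ResourceSummary(
        n_inputs=design.n_inputs,
        z_bound=bounds.z_bound,
        m_bound=bounds.m_bound,
        b_count=bounds.b_count,
        il_types_used=len(design.il_types()),
        ol_types_used=len(design.ol_types()),
        buf_types_used=buf,
        modules_used=design.m_design + buf,
    )


# ---------------------------------------------------------------------------
# Serialization: JSON and Graphviz DOT
# ---------------------------------------------------------------------------

def design_to_dict(design: CircuitDesign) -> dict:
    inv = design_inventory(design)
    return {
        "inputs": list(design.input_names),
        "outputs": list(design.output_names),
        "buffer": design.uses_buffer,
        "modules": [
            {
                "il_cells": [
                    {"input": c.input_index, "logic": c.logic.value}
                    for c in mod.il_cells
                ],
                "ol": mod.ol_cell,
                "output": mod.output_label,
            }
            for mod in design.modules
        ],
        "inventory": {
            "il_types": inv.il_types_used,
            "ol_types": inv.ol_types_used,
            "buf_types": inv.buf_types_used,
            "modules": inv.modules_used,
        },
    }


def design_to_json(design: CircuitDesign, indent: int = 2) -> str:
    return json.dumps(design_to_dict(design), indent=indent) + "\n"


def design_from_dict(data: Mapping) -> CircuitDesign:
    for key in ("inputs", "outputs", "modules"):
        if key not in data:
            raise ValueError(f"design JSON missing key {key!r}")
    modules = []
    for j, mod in enumerate(data["modules"]):
        if "il_cells" not in mod or "output" not in mod:
            raise ValueError(f"module {j} missing il_cells/output")
        cells = tuple(
            ThetaTerm(int(c["input"]), Logic(c["logic"])) for c in mod["il_cells"]
        )
        modules.append(
            ModuleSpec(cells, mod["output"], mod.get("ol", "OL_1"))
        )
    design = CircuitDesign(
        input_names=tuple(data["inputs"]),
        modules=tuple(modules),
        output_names=tuple(data["outputs"]),
        uses_buffer=bool(data.get("buffer", False)),
    )
    inv = data.get("inventory")
    if inv is not None:
        recomputed = design_inventory(design)
        stored = (inv.get("il_types"), inv.get("ol_types"), inv.get("modules"))
        fresh = (
            recomputed.il_types_used,
            recomputed.ol_types_used,
            recomputed.modules_used,
        )
        if stored != fresh:
            raise ValueError(
                f"stored inventory {stored} does not match modules {fresh}"
            )
    return design


def design_from_json(text: str) -> CircuitDesign:
    return design_from_dict(json.loads(text))


def design_to_dot(design: CircuitDesign) -> str:
    """Graphviz diagram: chambers as clusters, cells as nodes, wire edges."""
    lines = ["digraph consortium {", "  rankdir=LR;", "  node [shape=box];"]
    for j, mod in enumerate(design.modules):
        lines.append(f"  subgraph cluster_m{j} {{")
        lines.append(f'    label="module {j + 1} ({mod.output_label})";')
        ol_id = f"m{j}_ol"
        lines.append(f'    {ol_id} [label="{mod.ol_cell}", shape=ellipse];')
        for c in mod.il_cells:
            name = design.input_names[c.input_index]
            cell_id = f"m{j}_{c.input_index}"
            lines.append(f'    {cell_id} [label="{c.logic.value}({name})"];')
            lines.append(f'    {cell_id} -> {ol_id} [label="w"];')
        lines.append("  }")
    if design.uses_buffer:
        lines.append("  subgraph cluster_buf {")
        lines.append('    label="buffer chamber";')
        lines.append('    buf [label="BUF", shape=ellipse];')
        lines.append("  }")
        for j, mod in enumerate(design.modules):
            lines.append(f'  m{j}_ol -> buf [label="b"];')
    lines.append("}")
    return "\n".join(lines) + "\n"
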