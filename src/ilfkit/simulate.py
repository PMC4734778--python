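"""Steady-state simulation of a compiled consortium design.

Each module is an isolated chamber in which the input-layer cells pool a
single wiring molecule (an implicit OR over their secretions) that
represses the chamber's output-layer cell.  All chambers receive the same
stimulus mixture.  The circuit-level output is integrated either as the
maximum reporter level across a given output's chambers (transducer mode)
or, for secreted outputs, as the response of a saturating buffer cell to
the summed secreted output (buffer mode).  Integrated levels are mapped to
ternary logic states by fixed thresholds: below the low threshold (default
20% positive cells) is 0, above the high threshold (default 60%) is 1,
anything between is indeterminate and counts as a verification failure.

Only endpoint (steady-state) levels are computed; incubation dynamics are
assumed to have settled.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .compiler import CircuitDesign, Logic, ModuleSpec
from .library import CellKind, CellModel, LibrarySpec, hill_response
from .truthtable import TruthTable

INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class LogicThresholds:
    low: float = 20.0
    high: float = 60.0

    def __post_init__(self):
        if not 0 <= self.low < self.high <= 100:
            raise ValueError("need 0 <= low < high <= 100")


def logic_state(value: float, thresholds: LogicThresholds = LogicThresholds()):
    """Ternary readout: 1 above the high threshold, 0 below the low one."""
    if not 0 <= value <= 100:
        raise ValueError(f"readout {value} outside [0, 100]")
    if value > thresholds.high:
        return 1
    if value < thresholds.low:
        return 0
    return INDETERMINATE


@dataclass(frozen=True)
class StimulusVector:
    """Concentration of every external input (abstract units, >= 0)."""

    levels: Mapping[str, float]

    def __post_init__(self):
        clean = {k: float(v) for k, v in self.levels.items()}
        if any(v < 0 for v in clean.values()):
            raise ValueError("stimulus concentrations must be non-negative")
        object.__setattr__(self, "levels", clean)

    def __getitem__(self, label: str) -> float:
        return self.levels.get(label, 0.0)

    @classmethod
    def from_bits(
        cls,
        bits: Sequence[int],
        input_names: Sequence[str],
        lib: LibrarySpec,
        scale: float = 1.0,
    ) -> "StimulusVector":
        """Logic 1 -> the library's working concentration, logic 0 -> none."""
        if len(bits) != len(input_names):
            raise ValueError("bit vector length mismatch")
        return cls(
            {
                name: scale * lib.working_concentration[name] if bit else 0.0
                for name, bit in zip(input_names, bits)
            }
        )


@dataclass(frozen=True)
class ChamberResult:
    module_index: int
    output_label: str
    omega_total: float
    beta: float
    contributions: Mapping[str, float]  # IL cell name -> wire contribution


@dataclass(frozen=True)
class OutputResult:
    chambers: tuple[ChamberResult, ...]
    integrated: float
    state: object  # 0 | 1 | INDETERMINATE


@dataclass(frozen=True)
class SimulationResult:
    outputs: Mapping[str, OutputResult]
    mode: str  # "transducer" | "buffer"

    def state(self, output: str):
        return self.outputs[output].state


def _effective_stimulus(
    cell: CellModel, stimulus: StimulusVector, lib: LibrarySpec
) -> float:
    x = stimulus[cell.sensed_species]
    xt = lib.crosstalk.get(cell.name)
    if xt:
        x += sum(w * stimulus[label] for label, w in xt.items())
    return x


def simulate_chamber(
    module: ModuleSpec,
    stimulus: StimulusVector,
    lib: LibrarySpec,
    design_inputs: Sequence[str],
    fractions: Mapping[str, float] | None = None,
    module_index: int = 0,
    ol_fraction: float = 0.2,
) -> ChamberResult:
    """One chamber at steady state under a stimulus mixture.

    Each IL cell contributes ``fraction x max_wire_output x (response/100)``
    of wiring molecule; the pooled total drives the OL cell's repression
    curve.  By default the IL cells split the non-OL biomass equally.
    """
    cells = []
    for theta in module.il_cells:
        label = design_inputs[theta.input_index]
        if label not in lib.il_pairs:
            raise KeyError(f"library has no IL pair for input {label!r}")
        cells.append(lib.il_cell(label, theta.logic.value))
    m = len(cells)
    if fractions is None:
        il_budget = 1.0 - ol_fraction
        fractions = {c.name: il_budget / m for c in cells} if m else {}
    omega = 0.0
    contributions = {}
    for cell in cells:
        frac = fractions[cell.name]
        if frac < 0:
            raise ValueError(f"negative cell fraction for {cell.name}")
        x = _effective_stimulus(cell, stimulus, lib)
        y = hill_response(cell.params, x)
        contrib = frac * cell.max_wire_output * y / 100.0
        omega += contrib
        contributions[cell.name] = contrib
    ol = lib.ol_cells.get(module.ol_cell)
    if ol is None:
        raise KeyError(f"library has no OL cell {module.ol_cell!r}")
    beta = hill_response(ol.params, omega)
    return ChamberResult(
        module_index=module_index,
        output_label=module.output_label,
        omega_total=omega,
        beta=beta,
        contributions=contributions,
    )


def integrate_transducer(chambers: Sequence[ChamberResult]) -> float:
    """Transducer readout: the highest reporter level across chambers."""
    if not chambers:
        raise ValueError("no chambers to integrate")
    return max(c.beta for c in chambers)


def integrate_buffer(
    chambers: Sequence[ChamberResult], buf: CellModel | None
) -> float:
    """Buffer readout: step response of the buffer cell to summed output.

    The buffer saturates, so the readout is nearly independent of how many
    chambers fire once at least one does.
    """
    if buf is None:
        raise ValueError("library has no buffer cell")
    if buf.kind is not CellKind.BUF_ID:
        raise ValueError("integration cell must be a BUF_ID type")
    total = sum(c.beta for c in chambers)
    return hill_response(buf.params, total)


def simulate_circuit(
    design: CircuitDesign,
    stimulus: StimulusVector,
    lib: LibrarySpec,
    mode: str = "transducer",
    thresholds: LogicThresholds = LogicThresholds(),
    fractions: Mapping[str, float] | None = None,
) -> SimulationResult:
    """Simulate every chamber under one stimulus and integrate per output."""
    if mode not in ("transducer", "buffer"):
        raise ValueError("mode must be 'transducer' or 'buffer'")
    chambers = [
        simulate_chamber(
            mod, stimulus, lib, design.input_names,
            fractions=fractions, module_index=j,
        )
        for j, mod in enumerate(design.modules)
    ]
    outputs = {}
    for out in design.output_names:
        mine = tuple(c for c in chambers if c.output_label == out)
        if not mine:
            # constant-0 output: no chamber ever produces signal
            outputs[out] = OutputResult(chambers=(), integrated=0.0, state=0)
            continue
        if mode == "transducer":
            value = integrate_transducer(mine)
        else:
            value = integrate_buffer(mine, lib.buf_cell)
        outputs[out] = OutputResult(
            chambers=mine, integrated=value, state=logic_state(value, thresholds)
        )
    return SimulationResult(outputs=outputs, mode=mode)


# ---------------------------------------------------------------------------
# Exhaustive verification and crosstalk robustness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VerificationRow:
    bits: tuple[int, ...]
    output: str
    expected: int
    integrated: float
    state: object
    ok: bool


@dataclass(frozen=True)
class VerificationReport:
    rows: tuple[VerificationRow, ...]
    passed: bool
    n_pass: int
    n_total: int

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "bits": ["".join(map(str, r.bits)) for r in self.rows],
                "output": [r.output for r in self.rows],
                "expected": [r.expected for r in self.rows],
                "value": [r.integrated for r in self.rows],
                "state": [str(r.state) for r in self.rows],
                "pass": [r.ok for r in self.rows],
            }
        )


def verify_design(
    design: CircuitDesign,
    tt: TruthTable,
    lib: LibrarySpec,
    mode: str = "transducer",
    thresholds: LogicThresholds = LogicThresholds(),
) -> VerificationReport:
    """Simulate all 2^N working-concentration stimuli against the table.

    A combination passes only when the integrated state equals the expected
    bit exactly; an indeterminate readout is a failure.
    """
    if tuple(tt.input_names) != tuple(design.input_names):
        raise ValueError("design and truth table input names differ")
    n = design.n_inputs
    rows = []
    for m in range(1 << n):
        bits = tuple(m >> k & 1 for k in range(n))
        stim = StimulusVector.from_bits(bits, design.input_names, lib)
        result = simulate_circuit(design, stim, lib, mode=mode, thresholds=thresholds)
        for out in design.output_names:
            expected = int(m in tt.on_sets[out])
            res = result.outputs[out]
            rows.append(
                VerificationRow(
                    bits=bits,
                    output=out,
                    expected=expected,
                    integrated=res.integrated,
                    state=res.state,
                    ok=res.state == expected,
                )
            )
    n_pass = sum(r.ok for r in rows)
    return VerificationReport(
        rows=tuple(rows),
        passed=n_pass == len(rows),
        n_pass=n_pass,
        n_total=len(rows),
    )


def crosstalk_sweep(
    design: CircuitDesign,
    tt: TruthTable,
    lib: LibrarySpec,
    epsilons: Sequence[float],
    mode: str = "transducer",
    thresholds: LogicThresholds = LogicThresholds(),
) -> list[tuple[float, float]]:
    """Verification pass rate as uniform off-target crosstalk grows.

    For each weight the sweep rebuilds the library with every off-target
    entry set to that value and reruns full verification; returns
    ``(epsilon, pass_rate)`` pairs in the given order.
    """
    curve = []
    for eps in epsilons:
        if eps < 0:
            raise ValueError("crosstalk weight must be non-negative")
        perturbed = lib.with_uniform_crosstalk(eps)
        report = verify_design(design, tt, perturbed, mode=mode, thresholds=thresholds)
        curve.append((float(eps), report.n_pass / report.n_total))
    return curve
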