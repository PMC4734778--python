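"""Engineered cell types as steady-state Hill transfer functions.

Each cell type (input-layer ID/NOT sensors, output-layer reporter, buffer)
is characterised by a four-parameter Hill curve relating its stimulus
concentration to the percentage of responding cells:

    activation:  y(x) = y_low + (y_high - y_low) * x^n / (K^n + x^n)
    repression:  y(x) = y_low + (y_high - y_low) * K^n / (K^n + x^n)

with response floor/ceiling ``y_low``/``y_high`` (percent positive cells),
half-maximal concentration ``K`` (abstract units) and Hill coefficient
``n``.  Concentrations are abstract throughout; the library stores a
working concentration per input representing logic 1.

All numeric parameter defaults here are synthetic stand-ins constructed to
satisfy the digital-abstraction geometry (floor below the 20% threshold,
ceiling above 60%); they are not measured values.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np


class Mode(enum.Enum):
    ACTIVATION = "activation"
    REPRESSION = "repression"


class CellKind(enum.Enum):
    IL_ID = "IL_ID"
    IL_NOT = "IL_NOT"
    OL_NOT = "OL_NOT"
    BUF_ID = "BUF_ID"


class FitError(RuntimeError):
    """Hill fit failed to converge or had too few points."""


@dataclass(frozen=True)
class HillParams:
    y_low: float
    y_high: float
    K: float
    n: float
    mode: Mode

    def __post_init__(self):
        if not 0 <= self.y_low < self.y_high <= 100:
            raise ValueError("need 0 <= y_low < y_high <= 100")
        if self.K <= 0:
            raise ValueError("K must be positive")
        if self.n <= 0:
            raise ValueError("Hill coefficient must be positive")


def hill_response(params: HillParams, x):
    """Percent-positive response at concentration(s) ``x`` (scalar or array)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("concentrations must be non-negative")
    # compute on the ratio scale to stay finite for extreme x
    r = (x / params.K) ** params.n
    frac = r / (1.0 + r)
    if params.mode is Mode.REPRESSION:
        frac = 1.0 - frac
    y = params.y_low + (params.y_high - params.y_low) * frac
    return float(y) if y.ndim == 0 else y


def fit_hill(
    xs: Sequence[float],
    ys: Sequence[float],
    mode: Mode,
    max_nfev: int = 20000,
) -> tuple[HillParams, float]:
    """Least-squares four-parameter Hill fit.

    Returns the fitted parameters and the Pearson correlation ``r`` between
    fitted and observed responses.  Requires at least 4 points and a
    non-constant, non-negative concentration grid.
    """
    from scipy.optimize import curve_fit

    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size != ys.size:
        raise ValueError("xs and ys must have the same length")
    if xs.size < 4:
        raise FitError("need at least 4 points to fit 4 parameters")
    if np.any(xs < 0):
        raise ValueError("concentrations must be non-negative")
    if np.allclose(xs, xs[0]):
        raise FitError("concentration grid is constant")

    sign = 1.0 if mode is Mode.ACTIVATION else -1.0

    def model(x, y_low, dy, logK, n):
        r = np.power(np.maximum(x, 0.0) / np.exp(logK), n)
        frac = r / (1.0 + r)
        if sign < 0:
            frac = 1.0 - frac
        return y_low + dy * frac

    y_low0 = float(np.clip(ys.min(), 0, 99))
    dy0 = float(max(ys.max() - ys.min(), 1.0))
    pos = xs[xs > 0]
    logK0 = float(np.log(np.median(pos))) if pos.size else 0.0
    p0 = (y_low0, dy0, logK0, 2.0)
    bounds = ([0.0, 1e-6, -30.0, 0.05], [100.0, 100.0, 30.0, 30.0])
    try:
        popt, _ = curve_fit(
            model, xs, ys, p0=p0, bounds=bounds, max_nfev=max_nfev
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"Hill fit did not converge: {exc}") from exc
    y_low, dy, logK, n = popt
    y_high = min(y_low + dy, 100.0)
    params = HillParams(
        y_low=float(y_low),
        y_high=float(y_high),
        K=float(np.exp(logK)),
        n=float(n),
        mode=mode,
    )
    fitted = model(xs, *popt)
    if np.std(fitted) == 0 or np.std(ys) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(fitted, ys)[0, 1])
    return params, r


@dataclass(frozen=True)
class CellModel:
    """One engineered cell type: what it senses, what it makes, its curve."""

    name: str
    kind: CellKind
    sensed_species: str
    produced_species: str
    params: HillParams
    max_wire_output: float | None = None  # IL cells only: ceiling of wire secretion

    def __post_init__(self):
        expected = {
            CellKind.IL_ID: Mode.ACTIVATION,
            CellKind.IL_NOT: Mode.REPRESSION,
            CellKind.OL_NOT: Mode.REPRESSION,
            CellKind.BUF_ID: Mode.ACTIVATION,
        }[self.kind]
        if self.params.mode is not expected:
            raise ValueError(
                f"{self.kind.value} cell must have {expected.value} response"
            )
        if self.kind in (CellKind.IL_ID, CellKind.IL_NOT):
            if self.max_wire_output is None or self.max_wire_output <= 0:
                raise ValueError("IL cells need a positive max_wire_output")


DEFAULT_INPUTS = ("DOX", "PRO", "ALD", "aCa", "EST", "DEX")


@dataclass(frozen=True)
class LibrarySpec:
    """A complete cell library: ID/NOT pair per input, OL cells, buffer.

    ``crosstalk[cell_name][input_label]`` holds off-target response weights;
    the effective stimulus of an IL cell is its own input plus the weighted
    sum of the others.  Defaults to no crosstalk.
    """

    input_labels: tuple[str, ...]
    il_pairs: Mapping[str, Mapping[str, CellModel]]  # label -> {"ID","NOT"}
    ol_cells: Mapping[str, CellModel]  # name -> model
    buf_cell: CellModel | None
    working_concentration: Mapping[str, float]
    crosstalk: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "input_labels", tuple(self.input_labels))
        for label in self.input_labels:
            pair = self.il_pairs.get(label)
            if pair is None or "ID" not in pair or "NOT" not in pair:
                raise ValueError(f"input {label!r} needs both ID and NOT cells")
            if label not in self.working_concentration:
                raise ValueError(f"missing working concentration for {label!r}")
            if self.working_concentration[label] <= 0:
                raise ValueError("working concentrations must be positive")
        if not self.ol_cells:
            raise ValueError("need at least one OL cell")

    def il_cell(self, label: str, logic: str) -> CellModel:
        return self.il_pairs[label][logic]

    def crosstalk_weight(self, cell_name: str, input_label: str) -> float:
        return float(self.crosstalk.get(cell_name, {}).get(input_label, 0.0))

    def with_uniform_crosstalk(self, eps: float) -> "LibrarySpec":
        """Set every off-target IL weight to ``eps`` (on-target stays 1)."""
        xt: dict[str, dict[str, float]] = {}
        for label in self.input_labels:
            for logic in ("ID", "NOT"):
                cell = self.il_pairs[label][logic]
                xt[cell.name] = {
                    other: eps for other in self.input_labels if other != label
                }
        return replace(self, crosstalk=xt)


def _il_pair(label: str, K: float, n: float, wire_max: float) -> dict[str, CellModel]:
    id_params = HillParams(5.0, 85.0, K, n, Mode.ACTIVATION)
    not_params = HillParams(5.0, 85.0, K, n, Mode.REPRESSION)
    return {
        "ID": CellModel(
            name=f"IL_{label}_ID",
            kind=CellKind.IL_ID,
            sensed_species=label,
            produced_species="wire",
            params=id_params,
            max_wire_output=wire_max,
        ),
        "NOT": CellModel(
            name=f"IL_{label}_NOT",
            kind=CellKind.IL_NOT,
            sensed_species=label,
            produced_species="wire",
            params=not_params,
            max_wire_output=wire_max,
        ),
    }


def default_library(profile: str = "ideal_step") -> LibrarySpec:
    """Synthetic six-input default library.

    ``ideal_step`` uses steep curves (n = 8) approximating ideal digital
    stages; ``graded`` uses n = 2 curves with visible intermediate levels.
    Sensor half-max K = 10 concentration units, working concentration
    10 K; wire secretion ceiling 100 units per unit cell fraction.  The
    output-layer half-max (K = 7 wire units) sits between the pooled basal
    leakage of a fully silent chamber and the wire level of a single active
    sensor at the smallest per-cell fraction used (six sensors per chamber).
    """
    if profile not in ("ideal_step", "graded"):
        raise ValueError("profile must be 'ideal_step' or 'graded'")
    n_hill = 8.0 if profile == "ideal_step" else 2.0
    K_sensor = 10.0
    wire_max = 100.0
    il_pairs = {
        label: _il_pair(label, K_sensor, n_hill, wire_max)
        for label in DEFAULT_INPUTS
    }
    ol_params = HillParams(5.0, 85.0, 7.0, n_hill, Mode.REPRESSION)
    ol_cells = {
        "OL_1": CellModel("OL_1", CellKind.OL_NOT, "wire", "GFP", ol_params),
        "OL_2": CellModel("OL_2", CellKind.OL_NOT, "wire", "mCherry", ol_params),
        "OL_3": CellModel("OL_3", CellKind.OL_NOT, "wire", "beta", ol_params),
    }
    buf = CellModel(
        name="BUF",
        kind=CellKind.BUF_ID,
        sensed_species="beta",
        produced_species="GFP",
        # step-like in both profiles: the buffer is engineered for saturation
        params=HillParams(5.0, 85.0, 35.0, 8.0, Mode.ACTIVATION),
    )
    working = {label: 10.0 * K_sensor for label in DEFAULT_INPUTS}
    return LibrarySpec(
        input_labels=DEFAULT_INPUTS,
        il_pairs=il_pairs,
        ol_cells=ol_cells,
        buf_cell=buf,
        working_concentration=working,
    )


# ---------------------------------------------------------------------------
# Library validation against the digital-abstraction requirements
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationIssue:
    cell: str
    check: str  # "steepness", "noise_margin", "crosstalk"
    message: str


@dataclass(frozen=True)
class ValidationReport:
    issues: tuple[ValidationIssue, ...]
    margins: Mapping[str, float]  # cell -> worst-case margin (percent points)

    @property
    def passed(self) -> bool:
        return not self.issues


def _cell_states(cell: CellModel, lib: LibrarySpec) -> tuple[float, float]:
    """Response at logic-0 and logic-1 stimulus for one cell (percent)."""
    if cell.kind in (CellKind.IL_ID, CellKind.IL_NOT):
        hi = lib.working_concentration[cell.sensed_species]
    elif cell.kind is CellKind.OL_NOT:
        hi = 10.0 * cell.params.K
    else:  # buffer senses pooled secreted output
        hi = 10.0 * cell.params.K
    return hill_response(cell.params, 0.0), hill_response(cell.params, hi)


def validate_library(
    lib: LibrarySpec,
    low_threshold: float = 20.0,
    high_threshold: float = 60.0,
    steepness_min: float = 1.5,
    eps_max: float = 0.1,
) -> ValidationReport:
    """Check every cell against the digital-stage requirements.

    (i) step-like shape: Hill coefficient at least ``steepness_min``;
    (iii) noise margins: the two logic-state responses fall strictly on
    opposite sides of the low/high thresholds; (iv) specificity: no
    crosstalk weight above ``eps_max``.  The report lists all failures and
    each cell's worst-case margin to its nearer threshold.
    """
    issues: list[ValidationIssue] = []
    margins: dict[str, float] = {}
    cells = [
        lib.il_pairs[label][logic]
        for label in lib.input_labels
        for logic in ("ID", "NOT")
    ]
    cells += list(lib.ol_cells.values())
    if lib.buf_cell is not None:
        cells.append(lib.buf_cell)
    for cell in cells:
        if cell.params.n < steepness_min:
            issues.append(
                ValidationIssue(
                    cell.name,
                    "steepness",
                    f"Hill coefficient {cell.params.n:.2f} < {steepness_min}",
                )
            )
        y0, y1 = _cell_states(cell, lib)
        lo, hi = min(y0, y1), max(y0, y1)
        margin_low = low_threshold - lo
        margin_high = hi - high_threshold
        margins[cell.name] = min(margin_low, margin_high)
        if lo >= low_threshold:
            issues.append(
                ValidationIssue(
                    cell.name,
                    "noise_margin",
                    f"low state {lo:.1f}% not below the {low_threshold}% threshold",
                )
            )
        if hi <= high_threshold:
            issues.append(
                ValidationIssue(
                    cell.name,
                    "noise_margin",
                    f"high state {hi:.1f}% not above the {high_threshold}% threshold",
                )
            )
        for other, w in lib.crosstalk.get(cell.name, {}).items():
            if w > eps_max:
                issues.append(
                    ValidationIssue(
                        cell.name,
                        "crosstalk",
                        f"off-target weight {w:.2f} on {other} exceeds {eps_max}",
                    )
                )
    return ValidationReport(tuple(issues), margins)


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------

def _params_to_dict(p: HillParams) -> dict:
    return {
        "y_low": p.y_low,
        "y_high": p.y_high,
        "K": p.K,
        "n": p.n,
        "mode": p.mode.value,
    }


def _params_from_dict(d: Mapping) -> HillParams:
    return HillParams(
        float(d["y_low"]), float(d["y_high"]), float(d["K"]), float(d["n"]),
        Mode(d["mode"]),
    )


def _cell_to_dict(c: CellModel) -> dict:
    out = {
        "name": c.name,
        "kind": c.kind.value,
        "sensed": c.sensed_species,
        "produced": c.produced_species,
        "params": _params_to_dict(c.params),
    }
    if c.max_wire_output is not None:
        out["max_wire_output"] = c.max_wire_output
    return out


def _cell_from_dict(d: Mapping) -> CellModel:
    return CellModel(
        name=d["name"],
        kind=CellKind(d["kind"]),
        sensed_species=d["sensed"],
        produced_species=d["produced"],
        params=_params_from_dict(d["params"]),
        max_wire_output=d.get("max_wire_output"),
    )


def library_to_json(lib: LibrarySpec, indent: int = 2) -> str:
    data = {
        "inputs": list(lib.input_labels),
        "il_pairs": {
            label: {
                logic: _cell_to_dict(lib.il_pairs[label][logic])
                for logic in ("ID", "NOT")
            }
            for label in lib.input_labels
        },
        "ol_cells": {k: _cell_to_dict(v) for k, v in lib.ol_cells.items()},
        "buf_cell": _cell_to_dict(lib.buf_cell) if lib.buf_cell else None,
        "working_concentration": dict(lib.working_concentration),
        "crosstalk": {k: dict(v) for k, v in lib.crosstalk.items()},
    }
    return json.dumps(data, indent=indent) + "\n"


def library_from_json(text: str) -> LibrarySpec:
    data = json.loads(text)
    for key in ("inputs", "il_pairs", "ol_cells", "working_concentration"):
        if key not in data:
            raise ValueError(f"library JSON missing key {key!r}")
    return LibrarySpec(
        input_labels=tuple(data["inputs"]),
        il_pairs={
            label: {
                logic: _cell_from_dict(cd)
                for logic, cd in pair.items()
            }
            for label, pair in data["il_pairs"].items()
        },
        ol_cells={k: _cell_from_dict(v) for k, v in data["ol_cells"].items()},
        buf_cell=_cell_from_dict(data["buf_cell"]) if data.get("buf_cell") else None,
        working_concentration={
            k: float(v) for k, v in data["working_concentration"].items()
        },
        crosstalk={
            k: {kk: float(vv) for kk, vv in v.items()}
            for k, v in data.get("crosstalk", {}).items()
        },
    )
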