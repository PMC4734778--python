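"""Chamber simulation, integration rules, thresholds, verification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ilfkit import (
    INDETERMINATE,
    CompileOptions,
    Logic,
    LogicThresholds,
    ModuleSpec,
    StimulusVector,
    ThetaTerm,
    compile_circuit,
    crosstalk_sweep,
    integrate_buffer,
    integrate_transducer,
    logic_state,
    simulate_chamber,
    simulate_circuit,
    verify_design,
)

from conftest import table_from_bits

INPUTS3 = ("DEX", "EST", "PRO")


def make_module(*cells, ol="OL_1"):
    return ModuleSpec(tuple(cells), "f", ol)


def stim(bits, lib, names=INPUTS3):
    return StimulusVector.from_bits(bits, names, lib)


class TestLogicState:
    @pytest.mark.parametrize(
        "value,expected", [(70, 1), (10, 0), (40, INDETERMINATE)]
    )
    def test_default_thresholds(self, value, expected):
        assert logic_state(value) == expected

    def test_boundaries_are_exclusive(self):
        # exactly on a threshold is not a clean state
        assert logic_state(20.0) == INDETERMINATE
        assert logic_state(60.0) == INDETERMINATE
        assert logic_state(19.999) == 0
        assert logic_state(60.001) == 1

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            logic_state(101.0)
        with pytest.raises(ValueError):
            logic_state(-0.5)

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            LogicThresholds(60, 20)


class TestStimulus:
    def test_from_bits_uses_working_concentrations(self, ideal_library):
        s = stim((1, 0, 1), ideal_library)
        assert s["DEX"] == ideal_library.working_concentration["DEX"]
        assert s["EST"] == 0.0
        assert s["PRO"] == ideal_library.working_concentration["PRO"]

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            StimulusVector({"DEX": -1.0})

    def test_missing_input_reads_zero(self):
        assert StimulusVector({})["anything"] == 0.0


class TestChamber:
    def test_module_fires_when_all_literals_satisfied(self, ideal_library):
        # NOR(NOT(x0), NOT(x1)): both inputs present -> no wire -> OL on
        module = make_module(
            ThetaTerm(0, Logic.NOT), ThetaTerm(1, Logic.NOT)
        )
        res = simulate_chamber(
            module, stim((1, 1, 0), ideal_library), ideal_library, INPUTS3
        )
        assert res.omega_total < 5
        assert res.beta > 60

    def test_module_silent_when_literal_violated(self, ideal_library):
        module = make_module(
            ThetaTerm(0, Logic.NOT), ThetaTerm(1, Logic.NOT)
        )
        res = simulate_chamber(
            module, stim((0, 1, 0), ideal_library), ideal_library, INPUTS3
        )
        assert res.omega_total > 20
        assert res.beta < 20

    def test_empty_module_fires_constitutively(self, ideal_library):
        res = simulate_chamber(
            make_module(), stim((0, 0, 0), ideal_library), ideal_library, INPUTS3
        )
        assert res.omega_total == 0.0
        assert res.beta == pytest.approx(
            ideal_library.ol_cells["OL_1"].params.y_high
        )

    def test_wire_is_sum_of_contributions(self, ideal_library):
        module = make_module(
            ThetaTerm(0, Logic.ID), ThetaTerm(2, Logic.NOT)
        )
        res = simulate_chamber(
            module, stim((1, 0, 0), ideal_library), ideal_library, INPUTS3
        )
        assert res.omega_total == pytest.approx(sum(res.contributions.values()))

    def test_missing_cell_type_raises(self, ideal_library):
        module = make_module(ThetaTerm(0, Logic.ID))
        with pytest.raises(KeyError):
            simulate_chamber(
                module, StimulusVector({}), ideal_library, ("UNKNOWN",)
            )

    def test_negative_fraction_rejected(self, ideal_library):
        module = make_module(ThetaTerm(0, Logic.ID))
        cell = ideal_library.il_pairs["DEX"]["ID"]
        with pytest.raises(ValueError):
            simulate_chamber(
                module, stim((1, 0, 0), ideal_library), ideal_library, INPUTS3,
                fractions={cell.name: -0.1},
            )


class TestIntegration:
    def _chambers(self, betas):
        from ilfkit.simulate import ChamberResult

        return [
            ChamberResult(j, "f", 0.0, b, {}) for j, b in enumerate(betas)
        ]

    @pytest.mark.parametrize(
        "betas,expected", [([70, 15, 10], 70), ([10, 15, 12], 15), ([42], 42)]
    )
    def test_transducer_takes_highest_value(self, betas, expected):
        assert integrate_transducer(self._chambers(betas)) == expected

    def test_transducer_requires_chambers(self):
        with pytest.raises(ValueError):
            integrate_transducer([])

    def test_buffer_saturation(self, ideal_library):
        buf = ideal_library.buf_cell
        one = integrate_buffer(self._chambers([84, 6, 6]), buf)
        three = integrate_buffer(self._chambers([84, 84, 84]), buf)
        assert one > 60
        assert abs(three - one) < 5  # step-like: count of firing chambers irrelevant

    def test_buffer_silent_at_basal_input(self, ideal_library):
        buf = ideal_library.buf_cell
        assert integrate_buffer(self._chambers([6, 6, 6]), buf) < 20

    def test_buffer_missing_raises(self):
        with pytest.raises(ValueError):
            integrate_buffer(self._chambers([50]), None)


class TestSimulateCircuit:
    @pytest.mark.parametrize(
        "bits,expected",
        [((0, 0, 0), 0), ((1, 1, 0), 1), ((0, 1, 1), 1), ((1, 0, 0), 0)],
    )
    def test_majority_rows(self, majority, ideal_library, bits, expected):
        design = compile_circuit(majority)
        res = simulate_circuit(
            design, stim(bits, ideal_library), ideal_library
        )
        assert res.state("f") == expected

    def test_mux_routes_selected_input(self, mux, ideal_library):
        design = compile_circuit(mux)
        # selectors 00 -> route I0; only I0 present -> output 1
        bits = (0, 0, 1, 0, 0, 0)
        s = StimulusVector.from_bits(bits, mux.input_names, ideal_library)
        assert simulate_circuit(design, s, ideal_library).state("f") == 1
        # same selectors, I0 absent, I3 present -> output 0
        bits = (0, 0, 0, 0, 0, 1)
        s = StimulusVector.from_bits(bits, mux.input_names, ideal_library)
        assert simulate_circuit(design, s, ideal_library).state("f") == 0

    def test_invalid_mode(self, majority, ideal_library):
        design = compile_circuit(majority)
        with pytest.raises(ValueError):
            simulate_circuit(
                design, stim((0, 0, 0), ideal_library), ideal_library,
                mode="psychic",
            )


class TestVerification:
    def test_majority_all_rows_pass(self, majority, ideal_library):
        design = compile_circuit(majority)
        report = verify_design(design, majority, ideal_library)
        assert report.passed and report.n_total == 8

    def test_comparator_both_outputs_pass(self, comparator, ideal_library):
        design = compile_circuit(comparator)
        report = verify_design(design, comparator, ideal_library)
        assert report.passed
        assert report.n_total == 32  # 16 combinations x 2 outputs

    def test_mux_all_64_pass(self, mux, ideal_library):
        design = compile_circuit(mux)
        report = verify_design(design, mux, ideal_library)
        assert report.passed and report.n_total == 64

    def test_sabotaged_library_fails_with_rows_listed(self, majority):
        from dataclasses import replace
        from ilfkit import HillParams, Mode, default_library

        lib = default_library("ideal_step")
        # OL ceiling below the high threshold: the 1 state is unreachable
        bad_ol = replace(
            lib.ol_cells["OL_1"],
            params=HillParams(5, 50, 7, 8, Mode.REPRESSION),
        )
        lib = replace(lib, ol_cells={**lib.ol_cells, "OL_1": bad_ol})
        design = compile_circuit(majority)
        report = verify_design(design, majority, lib)
        assert not report.passed
        failing = [r for r in report.rows if not r.ok]
        assert failing and all(r.expected == 1 for r in failing)

    def test_mismatched_inputs_rejected(self, majority, mux, ideal_library):
        design = compile_circuit(majority)
        with pytest.raises(ValueError):
            verify_design(design, mux, ideal_library)

    def test_report_dataframe_shape(self, majority, ideal_library):
        design = compile_circuit(majority)
        df = verify_design(design, majority, ideal_library).to_dataframe()
        assert list(df.columns) == [
            "bits", "output", "expected", "value", "state", "pass"
        ]
        assert len(df) == 8


class TestDigitalAbstraction:
    def test_every_three_input_function_verifies(self, ideal_library):
        """The step-profile library realises all 256 functions exactly."""
        for bits in range(256):
            tt = table_from_bits(bits, 3, names=INPUTS3)
            design = compile_circuit(tt)
            report = verify_design(design, tt, ideal_library)
            assert report.passed, f"function {bits}: {report.n_pass}/{report.n_total}"

    def test_random_functions_up_to_six_inputs(self, ideal_library):
        rng = np.random.default_rng(2024)
        names6 = ("DOX", "PRO", "ALD", "aCa", "EST", "DEX")
        for n in (4, 5, 6):
            for _ in range(25):
                bits = int(rng.integers(0, 1 << (1 << n), dtype=np.uint64)) \
                    if n < 6 else None
                if n == 6:
                    on = frozenset(
                        int(m) for m in np.flatnonzero(rng.random(64) < 0.5)
                    )
                else:
                    on = frozenset(m for m in range(1 << n) if bits >> m & 1)
                from ilfkit import TruthTable

                tt = TruthTable(names6[:n], ("f",), {"f": on})
                design = compile_circuit(tt)
                report = verify_design(design, tt, ideal_library)
                assert report.passed

    def test_or_semantics_state_iff_some_chamber_fires(
        self, majority, ideal_library
    ):
        design = compile_circuit(majority)
        th = LogicThresholds()
        for m in range(8):
            bits = majority.assignment_of(m)
            res = simulate_circuit(
                design, stim(bits, ideal_library), ideal_library
            )
            chamber_states = [
                logic_state(c.beta, th) for c in res.outputs["f"].chambers
            ]
            assert (res.state("f") == 1) == (1 in chamber_states)

    def test_transducer_and_buffer_modes_agree_on_majority(
        self, majority, ideal_library
    ):
        td = compile_circuit(majority)
        bd = compile_circuit(majority, CompileOptions.secreted())
        for m in range(8):
            bits = majority.assignment_of(m)
            s = stim(bits, ideal_library)
            a = simulate_circuit(td, s, ideal_library, mode="transducer")
            b = simulate_circuit(bd, s, ideal_library, mode="buffer")
            assert a.state("f") == b.state("f")

    def test_raising_inputs_never_flips_one_to_zero(self, ideal_library):
        """Monotone Hill composition for single-module all-NOT designs."""
        tt = table_from_bits(0b10000000, 3, names=INPUTS3)  # AND of 3 inputs
        design = compile_circuit(tt)
        assert design.m_design == 1
        for scale in (1.0, 2.0, 5.0, 20.0):
            s = StimulusVector.from_bits(
                (1, 1, 1), INPUTS3, ideal_library, scale=scale
            )
            assert simulate_circuit(design, s, ideal_library).state("f") == 1


class TestMetricEquivalence:
    def test_rescaled_readout_preserves_logic_states(
        self, majority, ideal_library
    ):
        """Percent-positive vs arbitrary-unit readouts classify identically
        under any strictly increasing rescaling with rescaled thresholds."""
        design = compile_circuit(majority)
        th = LogicThresholds()

        def rescale(v):  # strictly increasing map [0,100] -> [0,100]
            return 100.0 * (v / 100.0) ** 0.7

        for m in range(8):
            bits = majority.assignment_of(m)
            res = simulate_circuit(
                design, stim(bits, ideal_library), ideal_library
            )
            v = res.outputs["f"].integrated
            scaled_th = LogicThresholds(rescale(th.low), rescale(th.high))
            assert logic_state(v, th) == logic_state(rescale(v), scaled_th)


class TestCrosstalk:
    def test_zero_crosstalk_matches_plain_verification(
        self, majority, ideal_library
    ):
        design = compile_circuit(majority)
        [(eps, rate)] = crosstalk_sweep(design, majority, ideal_library, [0.0])
        base = verify_design(design, majority, ideal_library)
        assert eps == 0.0 and rate == base.n_pass / base.n_total

    def test_full_crosstalk_breaks_graded_majority(
        self, majority, graded_library
    ):
        design = compile_circuit(majority)
        [(_, rate)] = crosstalk_sweep(design, majority, graded_library, [1.0])
        assert rate < 1.0

    def test_curve_is_non_increasing(self, majority, graded_library):
        design = compile_circuit(majority)
        curve = crosstalk_sweep(
            design, majority, graded_library, [0.0, 0.1, 0.3, 0.6, 1.0]
        )
        rates = [r for _, r in curve]
        assert all(a >= b for a, b in zip(rates, rates[1:]))

    def test_negative_epsilon_rejected(self, majority, ideal_library):
        design = compile_circuit(majority)
        with pytest.raises(ValueError):
            crosstalk_sweep(design, majority, ideal_library, [-0.1])
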