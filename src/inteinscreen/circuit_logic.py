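"""Boolean evaluation of intein-split transcription-factor logic circuits.

Splitting a sigma factor (e.g. a minimal ECF) at its linker and fusing
the halves to the two halves of a split intein makes a two-input AND
gate: only when both inducers drive expression of their chimeric half
does trans-splicing reconstitute the transcription factor and fire the
reporter.  Wiring several such gates with orthogonal inteins/ECFs gives
multi-input circuits; each reporter goes high when any of its gates
evaluates true (OR over gates).

The model is purely Boolean — leakiness and dynamic range are not
modelled.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .exceptions import FormatError, InputError, StateError

MAX_INPUTS = 16


@dataclass(frozen=True)
class GateSpec:
    """A two-input AND gate: split TF halves driven by two inputs."""

    gate_id: str
    tf: str
    intein: str
    n_half_driver: str
    c_half_driver: str
    output_reporter: str

    def __post_init__(self):
        if self.n_half_driver == self.c_half_driver:
            raise FormatError(
                f"gate {self.gate_id!r}: the two halves must be driven by "
                "different inputs"
            )


@dataclass
class CircuitSpec:
    inputs: list[str]
    gates: list[GateSpec]
    reporters: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.reporters:
            seen = []
            for g in self.gates:
                if g.output_reporter not in seen:
                    seen.append(g.output_reporter)
            self.reporters = seen
        if len(set(self.reporters)) != len(self.reporters):
            raise FormatError("reporters must be distinct")
        declared = set(self.inputs)
        for g in self.gates:
            for drv in (g.n_half_driver, g.c_half_driver):
                if drv not in declared:
                    raise FormatError(
                        f"gate {g.gate_id!r} driven by undeclared input {drv!r}"
                    )
            if g.output_reporter not in self.reporters:
                raise FormatError(
                    f"gate {g.gate_id!r} writes to undeclared reporter "
                    f"{g.output_reporter!r}"
                )


def evaluate_gate(gate: GateSpec, state: dict[str, bool]) -> bool:
    """AND of the two driver inputs; missing inputs are an error."""
    for drv in (gate.n_half_driver, gate.c_half_driver):
        if drv not in state:
            raise StateError(f"gate {gate.gate_id!r}: input {drv!r} not in state")
    return bool(state[gate.n_half_driver]) and bool(state[gate.c_half_driver])


def evaluate_circuit(circuit: CircuitSpec, state: dict[str, bool]) -> dict[str, bool]:
    """Reporter states for one input combination (OR over each reporter's gates)."""
    out = {r: False for r in circuit.reporters}
    for g in circuit.gates:
        if evaluate_gate(g, state):
            out[g.output_reporter] = True
    return out


def truth_table(circuit: CircuitSpec) -> pd.DataFrame:
    """All 2^n input combinations in binary order, with reporter outcomes."""
    n = len(circuit.inputs)
    if n > MAX_INPUTS:
        raise InputError(f"at most {MAX_INPUTS} inputs supported, got {n}")
    rows = []
    for bits in itertools.product([False, True], repeat=n):
        state = dict(zip(circuit.inputs, bits))
        row = {inp: b for inp, b in state.items()}
        row.update(evaluate_circuit(circuit, state))
        rows.append(row)
    return pd.DataFrame(rows, columns=circuit.inputs + circuit.reporters)


def three_input_demo_circuit() -> CircuitSpec:
    """The three-input / three-output demultiplexer wiring.

    Each inducer (arabinose, rhamnose, AHL) drives one pair of
    non-complementary split-ECF/split-intein halves, so every reporter
    requires exactly two inputs: BFP <- rha AND AHL (ECF17 x NrdJ-1),
    GFP <- ara AND rha (ECF20 x M86), RFP <- ara AND AHL
    (ECF16 x SspGyrB).  Of the 8 input combinations, the three two-input
    states each fire one reporter and the all-on state fires all three.
    """
    gates = [
        GateSpec("G_BFP", "ECF17mut", "NrdJ-1", "rha", "AHL", "BFP"),
        GateSpec("G_GFP", "ECF20mut", "M86", "ara", "rha", "GFP"),
        GateSpec("G_RFP", "ECF16mut", "SspGyrB", "ara", "AHL", "RFP"),
    ]
    return CircuitSpec(["ara", "rha", "AHL"], gates, ["BFP", "GFP", "RFP"])


# ------------------------------------------------------------------ JSON I/O
def circuit_from_json(path: str | Path) -> CircuitSpec:
    data = json.loads(Path(path).read_text())
    gates = [GateSpec(**g) for g in data["gates"]]
    return CircuitSpec(data["inputs"], gates, data.get("reporters", []))


def circuit_to_json(circuit: CircuitSpec, path: str | Path) -> None:
    data = {
        "inputs": circuit.inputs,
        "reporters": circuit.reporters,
        "gates": [vars(g) for g in circuit.gates],
    }
    Path(path).write_text(json.dumps(data, indent=2))
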