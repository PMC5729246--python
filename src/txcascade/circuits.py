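"""Circuit topologies: ordered cascades of input block, NOT gates and reporters.

Circuit ids follow the collection's naming: input block name, gate letters,
then ``r`` (RFP reporter only) or ``rg`` (reporter plus constitutive GFP
monitor), e.g. ``X_1_TLr`` = inducible input X_1 -> tet NOT gate -> lac NOT
gate -> RFP.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import yaml

from .params import GATE_INFO

GATE_KINDS = {"T": "not_gate_tet", "L": "not_gate_lac", "Tw": "not_gate_tet"}


@dataclass(frozen=True)
class Block:
    """One cascade element.

    ``device`` names the Hill parameter block governing this element's output
    promoter (input blocks and NOT gates), or the expressed protein for
    reporter/monitor blocks.  ``gamma`` is the degradation rate key of the
    protein this block expresses ('' for untagged proteins).
    """

    kind: str  # input_inducible | input_repressible | not_gate_tet | not_gate_lac | reporter_rfp | monitor_gfp
    device: str
    gamma_key: str = ""  # GlobalConstants attribute name, '' -> no active degradation


@dataclass(frozen=True)
class CircuitTopology:
    circuit_id: str
    input_device: str
    orientation: str  # of the input block's HSL-responsive promoter
    gates: tuple[str, ...]  # ordered gate device names, subset of T/L/Tw
    has_monitor: bool
    sigma_class: str  # lambda | lac | tet : LuxR cassette burden class

    def __post_init__(self) -> None:
        if len(self.gates) > 2:
            raise ValueError("at most two NOT gates per cascade")
        for g in self.gates:
            if g not in GATE_INFO:
                raise ValueError(f"unknown gate device {g!r}")
        suffix = "rg" if self.has_monitor else "r"
        if not self.circuit_id.endswith(suffix):
            raise ValueError(
                f"circuit_id {self.circuit_id!r} inconsistent with has_monitor={self.has_monitor}"
            )

    @property
    def blocks(self) -> list[Block]:
        """Ordered block list (input first, reporter last, optional monitor)."""
        kind = "input_inducible" if self.orientation == "inducible" else "input_repressible"
        out = [Block(kind=kind, device=self.input_device)]
        for g in self.gates:
            out.append(Block(kind=GATE_KINDS[g], device=g, gamma_key=GATE_INFO[g][0]))
        out.append(Block(kind="reporter_rfp", device="RFP"))
        if self.has_monitor:
            out.append(Block(kind="monitor_gfp", device="GFP"))
        return out

    @property
    def devices(self) -> tuple[str, ...]:
        """Hill devices this circuit depends on (input block + gates)."""
        return (self.input_device, *self.gates)

    @property
    def n_repressible(self) -> int:
        """Count of sign-inverting elements (repressible input + NOT gates)."""
        return int(self.orientation == "repressible") + len(self.gates)

    @property
    def expected_direction(self) -> int:
        """+1 if the noise-free cascade output rises with HSL, -1 if it falls."""
        return 1 if self.n_repressible % 2 == 0 else -1


def make_circuit_id(input_device: str, gates: tuple[str, ...], monitor: bool) -> str:
    gate_part = "".join(gates)
    return f"{input_device}_{gate_part}{'rg' if monitor else 'r'}"


def _registry_spec() -> dict:
    with resources.files("txcascade.data").joinpath("circuits.yaml").open() as fh:
        return yaml.safe_load(fh)


def build_circuit_collection(
    include_monitor_variants: bool = False,
    include_weak_tet_variants: bool = False,
) -> list[CircuitTopology]:
    """Instantiate the named circuit collection from the packaged registry.

    Returns the 6 training circuits followed by the 8 test circuits (reporter
    only); with ``include_monitor_variants`` each circuit is duplicated with
    the GFP monitor cassette appended; ``include_weak_tet_variants`` adds the
    weak-RBS tet gate redesigns (X_2_Twr, X_1_TwLr, X_rep_TwLr).
    """
    spec = _registry_spec()
    inputs = spec["input_blocks"]
    entries = [(e, role) for role in ("training", "test") for e in spec[role]]
    if include_weak_tet_variants:
        entries += [(e, e.get("role", "test")) for e in spec["weak_tet"]]

    out: list[CircuitTopology] = []
    for entry, _role in entries:
        dev = entry["input"]
        gates = tuple(entry.get("gates", []))
        variants = [False, True] if include_monitor_variants else [False]
        for monitor in variants:
            out.append(
                CircuitTopology(
                    circuit_id=make_circuit_id(dev, gates, monitor),
                    input_device=dev,
                    orientation=inputs[dev]["orientation"],
                    gates=gates,
                    has_monitor=monitor,
                    sigma_class=inputs[dev]["sigma_class"],
                )
            )
    return out


def training_ids(monitor: bool = False, weak_tet: bool = False) -> list[str]:
    spec = _registry_spec()
    entries = list(spec["training"])
    if weak_tet:
        entries += [e for e in spec["weak_tet"] if e.get("role") == "training"]
    return [make_circuit_id(e["input"], tuple(e.get("gates", [])), monitor) for e in entries]


def test_ids(monitor: bool = False, weak_tet: bool = False) -> list[str]:
    spec = _registry_spec()
    entries = list(spec["test"])
    if weak_tet:
        entries += [e for e in spec["weak_tet"] if e.get("role", "test") == "test"]
    return [make_circuit_id(e["input"], tuple(e.get("gates", [])), monitor) for e in entries]


def monitor_culture() -> CircuitTopology:
    """Strain carrying only the constitutive GFP monitor cassette.

    Its GFP output is the unloaded monitor level (D_hat = 1), which anchors
    the monitor synthesis rate S_m in burden-model fits; without it the
    input-block fit has an exact scaling degeneracy between the Hill rates,
    the Sigma terms and S_m.
    """
    return CircuitTopology(
        circuit_id="Mon_rg",
        input_device="none",
        orientation="inducible",
        gates=(),
        has_monitor=True,
        sigma_class="none",
    )


def registry(
    include_monitor_variants: bool = True, include_weak_tet_variants: bool = True
) -> dict[str, CircuitTopology]:
    """Circuit-id -> topology mapping over the full collection."""
    out = {
        t.circuit_id: t
        for t in build_circuit_collection(include_monitor_variants, include_weak_tet_variants)
    }
    if include_monitor_variants:
        mon = monitor_culture()
        out[mon.circuit_id] = mon
    return out
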