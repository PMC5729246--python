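"""Parameter containers for the cascade steady-state models.

A cascade block is characterised by a four-parameter Hill transfer function
(basal rate ``delta``, range ``alpha``, half-activation input ``K``, Hill
coefficient ``eta``).  The burden model adds per-gene resource-usage weights
``J`` (for the circuit-regulated genes tetR, lacI and RFP), lumped
dimensionless LuxR terms ``Sigma`` per input-block promoter class, and the
monitor cassette synthesis rate ``S_m``.  Global constants are the repressor
degradation rates (LVA tag) and the fluorophore maturation rates.

Parameters are exchanged with the fitting machinery as flat ``{name: value}``
dictionaries using dotted keys (``"X_1.alpha"``, ``"T.K"``, ``"Sigma.lac"``,
``"J_tet"``, ``"S_m"``).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from importlib import resources

import yaml

ORIENTATIONS = ("inducible", "repressible")

#: gate device name -> (degradation-rate constant attribute, J key)
GATE_INFO = {
    "T": ("gamma_tet", "J_tet"),
    "L": ("gamma_lac", "J_lac"),
    "Tw": ("gamma_tet", "J_tet_w"),
}


@dataclass(frozen=True)
class HillParams:
    """One regulated promoter's transfer function.

    ``eta`` is stored positive; ``orientation`` selects the sign of the
    exponent (rising response for ``inducible``, falling for ``repressible``).
    ``K`` is in nM for HSL-driven promoters and AU_R cell^-1 for
    repressor-driven ones.
    """

    delta: float
    alpha: float
    K: float
    eta: float
    orientation: str = "inducible"

    def __post_init__(self) -> None:
        if self.delta < 0 or self.alpha < 0:
            raise ValueError("delta and alpha must be non-negative")
        if self.K <= 0:
            raise ValueError("K must be positive")
        if self.eta <= 0:
            raise ValueError("eta must be positive (orientation carries the sign)")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}")


@dataclass(frozen=True)
class GlobalConstants:
    """Fixed rate constants shared by every circuit (min^-1)."""

    gamma_tet: float = 0.0173
    gamma_lac: float = 0.0533
    a: float = 0.0167
    a_G: float = 0.0462

    def __post_init__(self) -> None:
        if min(self.gamma_tet, self.gamma_lac, self.a, self.a_G) <= 0:
            raise ValueError("all rate constants must be positive")


@dataclass
class BurdenParams:
    """Resource-usage parameters of the shared-capacity denominator.

    ``sigma`` maps input-block promoter class (``lambda``/``lac``/``tet``) to
    the lumped, dimensionless LuxR burden term (J times the rescaled LuxR
    synthesis rate).  ``J_*`` are per-gene usage weights in AU_R^-1 cell min;
    ``s_m`` is the monitor cassette's GFP synthesis rate in AU_G cell^-1
    min^-1.
    """

    J_RFP: float = 0.0
    J_tet: float = 0.0
    J_lac: float = 0.0
    J_tet_w: float = 0.0
    sigma: dict[str, float] = field(default_factory=lambda: {"lambda": 0.0, "lac": 0.0, "tet": 0.0})
    s_m: float = 0.0

    def __post_init__(self) -> None:
        vals = [self.J_RFP, self.J_tet, self.J_lac, self.J_tet_w, self.s_m, *self.sigma.values()]
        if any(v < 0 for v in vals):
            raise ValueError("burden parameters must be non-negative")

    def J_for_gate(self, gate: str) -> float:
        return getattr(self, GATE_INFO[gate][1])


@dataclass
class CascadeParameters:
    """Full parameter set: Hill blocks, burden terms and global constants."""

    hill: dict[str, HillParams]
    burden: BurdenParams | None = None
    constants: GlobalConstants = field(default_factory=GlobalConstants)

    # -- flat-dictionary interface used by the fitting machinery ------------
    def to_flat(self) -> dict[str, float]:
        flat: dict[str, float] = {}
        for name, h in self.hill.items():
            flat[f"{name}.delta"] = h.delta
            flat[f"{name}.alpha"] = h.alpha
            flat[f"{name}.K"] = h.K
            flat[f"{name}.eta"] = h.eta
        if self.burden is not None:
            b = self.burden
            flat.update(
                {
                    "J_RFP": b.J_RFP,
                    "J_tet": b.J_tet,
                    "J_lac": b.J_lac,
                    "J_tet_w": b.J_tet_w,
                    "S_m": b.s_m,
                }
            )
            for cls, val in b.sigma.items():
                flat[f"Sigma.{cls}"] = val
        return flat

    def updated(self, flat: dict[str, float]) -> "CascadeParameters":
        """Return a copy with the given flat parameter values substituted."""
        new = copy.deepcopy(self)
        for key, value in flat.items():
            if "." in key and not key.startswith("Sigma."):
                dev, pname = key.split(".", 1)
                if dev not in new.hill:
                    raise KeyError(f"unknown device {dev!r}")
                new.hill[dev] = replace(new.hill[dev], **{pname: float(value)})
            elif key.startswith("Sigma."):
                if new.burden is None:
                    new.burden = BurdenParams()
                new.burden.sigma[key.split(".", 1)[1]] = float(value)
            elif key in ("J_RFP", "J_tet", "J_lac", "J_tet_w"):
                if new.burden is None:
                    new.burden = BurdenParams()
                setattr(new.burden, key, float(value))
            elif key == "S_m":
                if new.burden is None:
                    new.burden = BurdenParams()
                new.burden.s_m = float(value)
            else:
                raise KeyError(f"unknown parameter {key!r}")
        return new


def _load_device_params() -> dict:
    with resources.files("txcascade.data").joinpath("device_params.yaml").open() as fh:
        return yaml.safe_load(fh)


def default_parameters(column: str = "NBM_training") -> CascadeParameters:
    """Packaged parameter estimates for the cascade device collection.

    ``column`` is one of ``NBM_training``, ``BM_training``, ``BM_simultaneous``
    or ``NBM_weak_tet``.  The weak-tet column contains only the T_w gate; the
    other columns are full device sets.  BM columns include burden parameters;
    the T_w usage weight ``J_tet_w`` defaults to ``J_tet / 10`` (10-fold weaker
    RBS), since it was never estimated directly.
    """
    table = _load_device_params()
    try:
        col = table["columns"][column]
    except KeyError as exc:
        raise KeyError(
            f"unknown parameter column {column!r}; available: {sorted(table['columns'])}"
        ) from exc
    hill = {name: HillParams(**spec) for name, spec in col["hill"].items()}
    burden = None
    if "burden" in col:
        b = col["burden"]
        burden = BurdenParams(
            J_RFP=b["J_RFP"],
            J_tet=b["J_tet"],
            J_lac=b["J_lac"],
            J_tet_w=b.get("J_tet_w", b["J_tet"] / 10.0),
            sigma=dict(b["Sigma"]),
            s_m=b["S_m"],
        )
    constants = GlobalConstants(**table["constants"])
    return CascadeParameters(hill=hill, burden=burden, constants=constants)


def with_weak_tet(params: CascadeParameters) -> CascadeParameters:
    """Attach the weak-RBS tet gate (T_w) Hill block to a parameter set."""
    new = copy.deepcopy(params)
    new.hill.update(default_parameters("NBM_weak_tet").hill)
    return new
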