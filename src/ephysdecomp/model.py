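"""Single-compartment conductance-based neuron model.

Units follow the patch-clamp convention throughout the package: capacitance
in pF, conductances in nS, voltages in mV, currents in pA, time in ms.  With
these units ``dV/dt = I/C`` comes out directly in mV/ms.

The membrane equation is

    C dV/dt = I_inj - I_Na - I_DR - I_A - I_L

with a transient sodium current (g_Na * m^3 h * (V - E_Na)), a
delayed-rectifier potassium current (g_DR * n^4 * (V - E_K)), a fast
inactivating A-type potassium current (g_A * a^3 b * (V - E_K)) and an ohmic
leak.  Gating kinetics live in :mod:`ephysdecomp.kinetics`.

Default parameters describe a cultured cortical pyramidal neuron at room
temperature: resting potential near -65 mV, input resistance of order
100 MOhm, spike threshold reachable within a -200..400 pA step grid, and
action potentials 1-3 ms wide whose repolarization speeds up as g_A grows.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = ["NeuronModel", "apply_pharmacology", "DRUG_TARGETS"]


@dataclass(frozen=True)
class NeuronModel:
    """Parameters of the single-compartment model.

    Attributes
    ----------
    C : float
        Membrane capacitance (pF).
    g_Na, g_DR, g_A, g_L : float
        Maximal conductances (nS) of the transient Na+, delayed-rectifier
        K+, A-type K+, and leak conductances.
    E_Na, E_K, E_L : float
        Reversal potentials (mV).  The A-current and the delayed rectifier
        share E_K.
    """

    C: float = 100.0
    g_Na: float = 5000.0
    g_DR: float = 300.0
    g_A: float = 200.0
    g_L: float = 8.0
    E_Na: float = 55.0
    E_K: float = -90.0
    E_L: float = -64.0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("membrane capacitance C must be positive")
        for name in ("g_Na", "g_DR", "g_A", "g_L"):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be non-negative")
        if not (self.E_Na > 0 > self.E_K):
            raise ValueError("expected E_Na > 0 > E_K")

    def with_(self, **kwargs) -> "NeuronModel":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


#: drug name -> attribute of the conductance it blocks
DRUG_TARGETS = {"TTx": "g_Na", "4AP": "g_A"}


def apply_pharmacology(
    model: NeuronModel, drug: str, block_fraction: float = 1.0
) -> NeuronModel:
    """Return a new model with a channel blocker applied.

    ``TTx`` blocks the transient sodium conductance; ``4AP`` blocks the
    A-type potassium conductance (the delayed rectifier is taken as
    4-AP-resistant at the working concentration).  ``block_fraction`` scales
    the targeted maximal conductance by ``(1 - block_fraction)``.  The input
    model is not modified.
    """
    if drug not in DRUG_TARGETS:
        raise ValueError(
            f"unknown drug {drug!r}; supported drugs: {sorted(DRUG_TARGETS)}"
        )
    if not 0.0 <= block_fraction <= 1.0:
        raise ValueError("block_fraction must be in [0, 1]")
    target = DRUG_TARGETS[drug]
    return model.with_(**{target: getattr(model, target) * (1.0 - block_fraction)})
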