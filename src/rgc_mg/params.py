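"""Biophysical parameters of the single-compartment retinal ganglion cell model.

All parameters live in :class:`ModelParameters`, a validated, immutable record.
Units follow the conventions of conductance-based membrane models:

* conductances ``g*`` in mS/cm^2
* potentials ``E*``, ``Vrest`` in mV
* membrane capacitance ``Cm`` in uF/cm^2 (so ``dV/dt = -sum(I)/Cm`` is mV/ms
  when currents are in uA/cm^2)
* time constants in ms
* calcium concentrations in uM, extracellular Mg2+ and glutamate in mM

The synaptic half-activation constants are stored in mM internally; note that
the NMDA receptor's glutamate EC50 (2 uM) is therefore ``ec50_nmda = 0.002``.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field, model_validator


class ModelParameters(BaseModel):
    """All biophysical constants of the RGC model.

    Defaults describe a cell with classic squid-axon Na/K densities, an
    A-type potassium current, a small L-type Ca2+ conductance, a
    Ca2+-activated potassium current, dual-component (AMPA/NMDA)
    glutamatergic input with a Jahr-Stevens Mg2+ block on the NMDA
    component, and single-pool intracellular Ca2+ dynamics.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    # -- membrane & intrinsic conductances ---------------------------------
    cm: float = Field(1.0, gt=0, description="Membrane capacitance (uF/cm^2)")
    g_na: float = Field(120.0, ge=0, description="Max Na+ conductance (mS/cm^2)")
    g_kdr: float = Field(36.0, ge=0, description="Delayed-rectifier K+ conductance (mS/cm^2)")
    g_ka: float = Field(8.0, ge=0, description="A-type K+ conductance (mS/cm^2)")
    g_cal: float = Field(0.3, ge=0, description="L-type Ca2+ conductance (mS/cm^2)")
    g_kca: float = Field(0.3, ge=0, description="Ca2+-activated K+ conductance (mS/cm^2)")
    g_leak: float = Field(0.35, ge=0, description="Leak conductance (mS/cm^2)")

    # -- reversal potentials ------------------------------------------------
    e_na: float = Field(50.0, description="Na+ reversal potential (mV)")
    e_k: float = Field(-77.0, description="K+ reversal potential (mV)")
    e_ca: float = Field(120.0, description="Ca2+ reversal potential (mV)")
    e_leak: float = Field(-54.4, description="Leak reversal potential (mV)")
    e_exc: float = Field(0.0, description="Excitatory synaptic reversal potential (mV)")
    v_rest: float = Field(-65.0, description="Resting membrane potential (mV)")

    # -- synaptic receptors -------------------------------------------------
    g_ampa: float = Field(0.25, ge=0, description="Max AMPA conductance (mS/cm^2)")
    g_nmda: float = Field(1.2, ge=0, description="Max NMDA conductance (mS/cm^2)")
    ec50_ampa: float = Field(0.5, gt=0, description="AMPA glutamate EC50 (mM)")
    ec50_nmda: float = Field(0.002, gt=0, description="NMDA glutamate EC50 (mM; = 2 uM)")
    tau_rise_ampa: float = Field(0.3, gt=0, description="AMPA gating rise time constant (ms)")
    tau_decay_ampa: float = Field(3.0, gt=0, description="AMPA gating decay time constant (ms)")
    tau_rise_nmda: float = Field(5.0, gt=0, description="NMDA gating rise time constant (ms)")
    tau_decay_nmda: float = Field(80.0, gt=0, description="NMDA gating decay time constant (ms)")

    # -- Jahr-Stevens Mg2+ block -------------------------------------------
    eta: float = Field(0.28, gt=0, description="Mg2+ block concentration factor (1/mM)")
    gamma: float = Field(0.062, gt=0, description="Mg2+ block voltage factor (1/mV)")

    # -- calcium dynamics ---------------------------------------------------
    f_ca: float = Field(0.15, ge=0, le=1, description="Fractional Ca2+ current through NMDA receptors")
    k_ca_nmda: float = Field(0.012, ge=0, description="NMDA current -> [Ca2+] scaling (uM cm^2 / uA / ms)")
    k_ca_cal: float = Field(0.003, ge=0, description="L-type current -> [Ca2+] scaling (uM cm^2 / uA / ms)")
    ca_rest: float = Field(0.05, gt=0, description="Resting intracellular [Ca2+] (uM)")
    tau_ca: float = Field(200.0, gt=0, description="Ca2+ clearance time constant (ms)")
    kd_kca: float = Field(0.5, gt=0, description="Half-activation [Ca2+] of the KCa current (uM)")

    @model_validator(mode="after")
    def _check_ordering(self) -> "ModelParameters":
        if not (self.e_k < self.v_rest < self.e_na):
            raise ValueError("expected E_K < V_rest < E_Na")
        return self


DEFAULT_PARAMETERS = ModelParameters()
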