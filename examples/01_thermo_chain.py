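"""Derive the superoxide gold-oxidation constant chain.

Starting from reaction-level inputs only (the enthalpy/entropy sums of the
low-pH superoxide reaction, two complexation constants, water
autoionization and the Au0/Au3+ standard potential), the chain yields the
equilibrium constants of both oxidation routes and the Nernst line of the
superoxide/water couple.
"""

from aurox import gold_oxidation_chain, load_database

db = load_database()
chain = gold_oxidation_chain(db)

print("Derived constant chain (25 degC):")
for name, value in chain.items():
    print(f"  {name:16s} {value:10.4f}")

print(
    "\nReading: gold oxidation by superoxide at low pH has logK =",
    f"{chain['logK_r3']:.2f} (favourable), while the dioxygen route to",
    f"Au(OH)4- has logK = {chain['logK_r2']:.2f} (strongly unfavourable),",
    "so superoxide, not O2, is the feasible Earth-surface oxidant.",
)
print(
    f"The O2-/H2O couple line 4 pH + {chain['line_eh_coeff']:.1f} Eh =",
    f"{chain['logK0_o2m_h2o']:.2f} runs from Eh = {chain['eh_ph0']:.2f} V",
    f"at pH 0 to {chain['eh_ph14']:.2f} V at pH 14.",
)
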