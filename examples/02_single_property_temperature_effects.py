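"""How one channel property's temperature sensitivity shapes velocity.

Each property is given a strong Q10 of 4 while all others stay
temperature-insensitive; velocity is measured from 5 to 30 degC.  Na
activation speed (tau_m) and Na conductance accelerate conduction when
warmed, leak conductance and Na inactivation slow it, and the Potassium
properties barely matter.
"""

from thermaxon import AxonSpec, ChannelSet, MembraneSpec, Q10Set, simulate_batch

axon, membrane, channels = AxonSpec(), MembraneSpec(), ChannelSet()
amp = 4.0  # nA, comfortably suprathreshold for the 3 um cable

properties = ["tau_m", "g_Na", "g_leak", "tau_h", "g_K", "tau_n"]
sets = [Q10Set()] + [Q10Set(**{p: 4.0}) for p in properties]

print("velocity (m/s) by temperature; each row scales ONE property with Q10=4")
print(f"{'model':>10s}" + "".join(f"{T:>8.0f}C" for T in (5, 10, 15, 20, 25, 30)))
rows = {name: [] for name in ["baseline"] + properties}
for T in (5.0, 10.0, 15.0, 20.0, 25.0, 30.0):
    res = simulate_batch(axon, membrane, channels, sets, T, amp)
    for name, r in zip(["baseline"] + properties, res):
        rows[name].append(r.velocity_m_per_s if r.status == "ok" else float("nan"))
for name, vv in rows.items():
    print(f"{name:>10s}" + "".join(f"{v:9.3f}" for v in vv))
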