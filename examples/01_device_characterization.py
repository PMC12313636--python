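"""Characterize the volatile NbOx memristor model.

Evaluates the device law at its calibrated constants: the pinched
hysteresis loop under sinusoidal drive, the sigmoidal steady-state of the
internal state (the analogue of the potassium gate's activation curve), and
the voltage-dependent effective time constant.
"""

import numpy as np

import memhh as M

nbox = M.MemristorParams.preset("nbox")

print("NbOx constants:", nbox.to_dict())
print(f"current at read bias (w={nbox.w_min}, V=0.7 V): "
      f"{M.device_current(nbox, nbox.w_min, 0.7):.3f} uA")

# steady-state activation: w_min at 0 V rising to w_max - the sigmoid that
# lets the device mimic the K channel's n-gate
for V in (0.0, 0.5, 1.0, 2.0, 4.0, 8.0):
    print(f"  V = {V:4.1f} V: w_inf = {M.steady_state_w(nbox, V):.3f}, "
          f"tau_eff = {M.effective_time_constant(nbox, V):7.2f} ms")

# pinched hysteresis loop at a drive period comparable to tau
tr = M.hysteresis_trace(nbox, amplitude=2.0, freq=1.0 / nbox.tau, dt=0.002,
                        cycles=3)
n = int(nbox.tau / 0.002)
area = abs(np.trapezoid(tr["i"][-n:], tr["V"][-n:]))
print(f"hysteresis loop area over one cycle: {area:.2f} uA*V "
      "(nonzero area = memory; i = 0 whenever V = 0 = pinched)")
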