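"""Decompose a skin-conductance record into phasic and tonic components.

The raw signal is modelled as tonic drift + sparse non-negative driver
convolved with a biexponential SCR kernel + residual, solved as a convex
quadratic program.  Here we build a signal with two known SCRs and check
that the decomposition finds them.
"""

import numpy as np

from tostab import BatemanParams, bateman_kernel, decompose_eda

rate = 4.0                       # Hz, wristband GSR sampling rate
n = 240                          # 60 s record
t = np.arange(n) / rate
kernel = bateman_kernel(BatemanParams(tau_rise=0.7, tau_decay=2.0), rate)

rng = np.random.default_rng(0)
signal = 2.0 + 0.005 * t         # tonic level with slow drift
for onset_s, amp in [(10.0, 0.8), (35.0, 0.5)]:
    i = int(onset_s * rate)
    signal[i:i + len(kernel)] += amp * kernel[: n - i]
signal += 0.01 * rng.standard_normal(n)

dec = decompose_eda(signal, rate)
print(f"objective {dec.objective:.4f}, "
      f"KKT residual {dec.diagnostics['kkt_residual']:.1e}, "
      f"driver l1 mass {dec.diagnostics['l1_driver']:.3f}")

peaks = np.flatnonzero(dec.driver > 0.1)
print("driver mass above 0.1 uS at t =", np.round(peaks / rate, 2), "s")
print(f"phasic energy fraction: {(dec.phasic**2).sum() / (signal**2).sum():.3f}")
print(f"closure max |y - (r+t+e)|: "
      f"{np.abs(dec.raw - dec.phasic - dec.tonic - dec.residual).max():.1e}")
# The driver concentrates at the two seeded SCR onsets (10 s and 35 s); the
# drift lands in the tonic component and the closure holds to machine
# precision.
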