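"""Build the two eustatic forcings and summarize their structure.

The composite sinusoid (long 1 Myr / 20 m cycle plus short 0.112 Myr / 2 m
cycle) drives a platform with two prolonged lowstand gaps. The glacioeustatic
stand-in emulates Pleistocene forcing: 41 kyr cycles growing in amplitude,
then quasi-100-kyr cycles with a 140 m range over the last 0.8 Myr.
"""

import numpy as np

from stratmode import sinusoidal_sealevel, synthetic_glacioeustatic_sealevel

curve_a = sinusoidal_sealevel()
print("composite sinusoid:")
print(f"  duration {curve_a.duration:.2f} Myr at dt = {curve_a.dt} Myr "
      f"({curve_a.elevations.size} samples)")
print(f"  range [{curve_a.elevations.min():+.1f}, "
      f"{curve_a.elevations.max():+.1f}] m (components add to at most 22 m)")

curve_b = synthetic_glacioeustatic_sealevel()
young = curve_b.elevations[curve_b.times >= curve_b.duration - 0.8]
old = curve_b.elevations[curve_b.times < curve_b.duration - 0.8]
print("glacioeustatic stand-in:")
print(f"  duration {curve_b.duration:.2f} Myr, mean "
      f"{curve_b.elevations.mean():+.1e} m (normalized to 0)")
print(f"  older segment peak-to-trough {old.max() - old.min():6.1f} m (41 kyr cycles)")
print(f"  youngest 0.8 Myr peak-to-trough {young.max() - young.min():6.1f} m "
      f"(quasi-100-kyr cycles)")
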