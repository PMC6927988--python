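"""Decompose the AP rising phase into AIS and somatodendritic components.

The somatic upstroke of a pyramidal-cell AP has two kinetic components:
the axon-initial-segment (AIS) potential arrives first, then the
somatodendritic (SD) potential takes over.  Their breakpoint shows as a
trough of d2V/dt2.  With b the peak dV/dt of the upstroke and a the SD
component's maximal slope, the ratio a/b indexes the perisomatic sodium
contribution.
"""

from spikephase import NeuronParams, ProtocolSpec, simulate_cell
from spikephase.phase import first_ap_of_train, slope_sd_ratio

rec, _ = simulate_cell(NeuronParams(), ProtocolSpec.default_ladder(), seed=7)

sweep, first_ap, approx = first_ap_of_train(rec)  # first AP of the 7-AP train
dec = slope_sd_ratio(sweep, first_ap)
bp = dec.breakpoint

print(f"analysed sweep: {sweep.step_amplitude:.0f} pA "
      f"({'approximate' if approx else 'exact'} 7-AP train)")
print(f"breakpoint      {bp.voltage:7.1f} mV at dV/dt = {bp.dvdt_value:.0f} mV/ms"
      f"  (d2V/dt2 trough, prominence {bp.prominence:.0f})")
print(f"b (peak slope)  {dec.b:7.0f} mV/ms")
print(f"a (SD slope)    {dec.a:7.0f} mV/ms   convention: {dec.convention}")
print(f"b - a (AIS)     {dec.ais_component:7.0f} mV/ms")
print(f"Slope_SD ratio  {dec.slope_sd_ratio:7.3f}   (a/b; rises with the "
      f"somatic share of Na conductance)")
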