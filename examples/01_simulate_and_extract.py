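"""Simulate one model L5 pyramidal cell and extract its intrinsic
properties.

Runs the default two-compartment neuron through the standard step
protocol (-100 pA plus 50 -> 1,500 pA in 50 pA increments at 50 kHz) and
prints the passive and action-potential measurements an
electrophysiologist would report for a real recording.
"""

from spikephase import (
    NeuronParams,
    ProtocolSpec,
    passive_features,
    simulate_cell,
)
from spikephase.spikes import extract_cell_features

rec, truth = simulate_cell(NeuronParams(), ProtocolSpec.default_ladder(),
                           seed=7, cell_id="demo")

pf = passive_features(rec)
print(f"RMP             {pf.rmp:8.1f} mV    (resting potential, no current)")
print(f"Rin             {pf.input_resistance:8.0f} MOhm  "
      f"(steady-state dV/dI at -100 pA)")
print(f"sag ratio       {pf.sag:8.3f}       (H-current signature; "
      f"prominent: {pf.prominent_h})")

fs = extract_cell_features(rec)
tr, ap = fs.train, fs.rheobase_ap
print(f"rheobase        {tr.rheobase:8.0f} pA    (smallest spiking step)")
print(f"spike latency   {tr.spike_latency:8.1f} ms")
print(f"threshold       {ap.threshold_voltage:8.1f} mV    (V at dV/dt = 20 V/s)")
print(f"peak amplitude  {ap.peak_amplitude:8.1f} mV    (peak - threshold)")
print(f"half-width      {ap.half_width:8.2f} ms")
print(f"mAHP            {ap.mahp:8.1f} mV    (threshold - trough, 100 ms window)")
print(f"dV/dt max/min   {ap.dvdt_max:6.0f} / {ap.dvdt_min:.0f} mV/ms")
print(f"7-AP train at   {tr.n7_current:8.0f} pA    "
      f"ISI1 {tr.isi_1:.1f} ms, ISI6 {tr.isi_6:.1f} ms, "
      f"accommodation {tr.accommodation_ratio:.2f}")
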