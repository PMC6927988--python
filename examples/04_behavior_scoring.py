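"""Score the three behavioral endpoints from event-level logs.

Prepulse inhibition (PPI) of the acoustic startle response, radial-arm
maze working-memory errors, and open-field jump time, each computed by
its defining arithmetic rule on synthetic session logs.
"""

import numpy as np

from spikephase import (
    BeamBreakLog,
    MazeSession,
    StartleSession,
    jump_time,
    ppi_percent,
    working_memory_errors,
)
from spikephase.behavior import maze_summary

# --- PPI: startle amplitude 100 alone, 25 after an 82 dB prepulse ----------
session = StartleSession(
    trial_types=["startle_only"] * 4 + ["prepulse_82"] * 4,
    amplitudes=np.array([95.0, 105.0, 100.0, 100.0, 24.0, 26.0, 25.0, 25.0]),
)
ppi = ppi_percent(session, "prepulse_82")
print(f"PPI at 82 dB prepulse: {ppi:.1f} %  "
      "(100 - prepulse mean / startle-only mean x 100)")

# --- radial arm maze: re-entering a visited arm is one error ---------------
days = [
    MazeSession([1, 3, 5, 3, 7, 2, 8, 4, 6], np.arange(9) * 30.0),
    MazeSession([2, 4, 6, 8, 1, 3, 5, 7], np.arange(8) * 25.0),
]
df = maze_summary(days)
for _, row in df.iterrows():
    print(f"maze day {int(row.day)}: {int(row.errors)} working-memory "
          f"error(s), completed in {row.completion_time:.0f} s")
print(f"average daily errors over {len(days)} days: "
      f"{df.attrs['average_daily_errors']:.1f}")

# --- open field: Z-beam breaks with no X/Y breaks = airborne ---------------
ts = np.concatenate([np.arange(0, 2000.0, 100.0),      # 2 s of jumping
                     np.arange(10_000.0, 10_500.0, 100.0)])  # walking
axes = ["Z"] * 20 + ["X"] * 5
log = BeamBreakLog(ts, axes)
print(f"jump time: {jump_time(log, bin_ms=100.0):.1f} s "
      "(bins with Z-only beam breaks)")
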