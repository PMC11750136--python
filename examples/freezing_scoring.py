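"""Score freezing from a per-frame pixel-change series.

An animal counts as freezing when the fraction of pixels changing between
frames stays below 0.1% for more than 1 s. The simulator programs bouts into
a 25 fps series; the detector recovers them and reports percent freezing per
protocol phase.
"""

from recogmem import synthetic as syn
from recogmem.freezing import detect_freezing, percent_freezing
from recogmem.io_formats import PhaseWindow

bouts = [(30.0, 42.0), (90.0, 95.0), (180.0, 210.0)]
series = syn.simulate_pixelchange(bouts, duration_s=300.0, fps=25.0, seed=0)

result = detect_freezing(series, fps=25.0, threshold=0.001, min_dur_s=1.0)
phases = [
    PhaseWindow(label="baseline", start_s=0.0, end_s=120.0),
    PhaseWindow(label="tone_trace", start_s=120.0, end_s=300.0),
]
pct = percent_freezing(result, phases)

print("programmed bouts:", bouts)
print("detected bouts:  ", [(float(s), float(e)) for s, e in result.bouts])
for label, value in pct.items():
    print(f"% freezing in {label:11s} {value:5.1f}%")

# The detector recovers the programmed bouts to the frame; bouts straddling a
# phase boundary contribute only their overlap to that phase's percentage.
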