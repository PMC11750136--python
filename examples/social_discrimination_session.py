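"""Analyze one simulated social-discrimination session end to end.

Simulates a 5-minute discrimination phase (novel vs familiar conspecific in
pencil chambers at opposite corners of a 50 x 50 cm arena, nose tracked at
60 fps, fiber photometry recorded alongside), then runs the full pipeline:
zone assignment, discrimination index, signal conditioning, calcium-event
detection, and the occupancy/event heatmap correlation.
"""

from recogmem import synthetic as syn
from recogmem.pipeline import analyze_session

sess = syn.simulate_discrimination_session(seed=2, duration_s=300.0)
res = analyze_session(sess.track, sess.layout, sess.signal)

print(f"novel-zone time:       {res.occupancy.time_in('novel'):7.1f} s")
print(f"familiar-zone time:    {res.occupancy.time_in('familiar'):7.1f} s")
print(f"discrimination index:  {res.indices['discrimination_index']:.3f}")
print(f"distance traveled:     {res.indices['distance_cm']:7.1f} cm")
print(f"calcium events:        {res.events.n_events} detected "
      f"({len(sess.true_event_times)} simulated)")
print(f"zone event ratio:      {res.indices['zone_event_ratio']:.2f} (novel/familiar)")
print(f"median column r:       {res.median_column_r:.3f}")

# The discrimination index is novel / (novel + familiar) interaction time:
# 0.5 is chance, values near 0.7 reflect the 2:1 novelty preference the
# simulator programs. The zone event ratio exceeds the time ratio because
# calcium events are 3x more frequent inside the novel interaction zone, and
# the column correlation shows event maps tracking occupancy across space.
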