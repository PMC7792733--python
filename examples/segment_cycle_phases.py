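"""Partition one cardiac cycle into its six mechanical phases.

The boundaries are the valve events (MVC, AVO, AVC, MVO) and the ECG
landmarks (QRS onsets, P-wave onset) of one beat, here a typical resting
cycle with an RR interval of 850 ms.
"""

from strainpost import EventTiming, segment_phases

events = EventTiming(
    qrs1=0, mvc=30, avo=80, avc=380, mvo=460, p_onset=700, qrs2=850
)
phases = segment_phases(events)

print(phases.format_report())
print()
print(f"cycle length: {events.cycle_length:.0f} ms")
print(f"sum of phase durations: {sum(phases.durations.values()):.0f} ms")
# The six durations partition the RR interval exactly: ejection (Ejec)
# dominates systole, early filling (E) dominates diastole.
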