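"""Write a marker table and event log to disk, read them back, and compute a
pharyngeal transit time from the recorded events."""

import tempfile
from pathlib import Path

from deglukin import (
    EventLog,
    read_events,
    read_recording,
    transit_time,
    write_events,
    write_recording,
)
from deglukin.phantom import PhantomConfig, simulate_recording

rec, _ = simulate_recording(PhantomConfig(duration=3.0, noise_sigma_px=0.3, seed=5))
rec.events = EventLog(entries={"bolus cross the mandible angle": 30,
                               "bolus tail cross the UES": 60})

with tempfile.TemporaryDirectory() as d:
    markers, events = Path(d) / "markers.csv", Path(d) / "events.csv"
    write_recording(rec, markers)
    write_events(rec.events, events)
    print(f"marker table: {len(markers.read_text().splitlines())} lines "
          f"(schema frame,marker,u,v, '# fps=' header)")

    back = read_recording(markers)
    back.events = read_events(events)
    assert back.frames[0].markers == rec.frames[0].markers  # exact round trip

    seconds, reversed_flag = transit_time(
        back.events, "bolus cross the mandible angle",
        "bolus tail cross the UES", back.fps,
    )
    print(f"pharyngeal transit time: {seconds:.3f} s "
          f"({back.events.frame_of('bolus tail cross the UES') - back.events.frame_of('bolus cross the mandible angle')} frames at {back.fps:.0f} fps)")
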