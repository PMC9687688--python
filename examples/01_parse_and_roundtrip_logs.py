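"""Parse a Tappy-style keystroke log and write it back unchanged.

Builds a tiny synthetic subject, serializes it to the 8-column text
format, re-parses it, and shows the first events.
"""

import tempfile
from pathlib import Path

from wavetap import SimConfig, parse_log, simulate_cohort, write_log

log = simulate_cohort(SimConfig(n_healthy=1, n_parkinson=0, events_per_subject=5, seed=1))[0]

with tempfile.TemporaryDirectory() as d:
    path = write_log(log, Path(d) / f"{log.subject_id}.txt")
    print(f"--- {path.name} ---")
    print(path.read_text())
    back = parse_log(path, log.label)

print(f"re-parsed {len(back)} events; identical to original: {back.events == log.events}")
print("each line: subject, date, time, key region, hold ms, transition, latency ms, flight ms")
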