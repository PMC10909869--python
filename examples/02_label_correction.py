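"""Correct longitudinal diagnosis labels and link scans to diagnoses.

A subject on a monotone disease path occasionally receives an isolated
discordant diagnosis. The correction rule flips a label when at least one
of the two preceding AND one of the two following original labels disagree
with it — a single simultaneous pass, so corrections never cascade.
"""

from neurofuse.cohort import assign_scan_label, correct_labels
from neurofuse.synth import DiagnosisEvent, ScanRecord

# an isolated false negative at day 800 inside a positive run
timeline = [DiagnosisEvent("subj01", d, l) for d, l in
            [(0, 0), (400, 1), (800, 0), (1200, 1), (1600, 1)]]
corrected = correct_labels(timeline)
print("days:            ", [e.day for e in timeline])
print("raw labels:      ", [e.label for e in timeline])
print("corrected labels:", [e.label for e in corrected])
# the day-800 negative flips to positive (positives on both sides);
# the day-400 positive ALSO satisfies the symmetric rule (a negative on
# each side among the originals) and flips down in the same pass

scan = ScanRecord("subj01", "MRI", day=900)
label = assign_scan_label(scan, corrected)
print(f"scan at day {scan.day} -> label {label} "
      f"(temporally closest corrected diagnosis, day 800)")
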