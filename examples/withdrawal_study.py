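"""Screen a simulated medicated-feed study and read off withdrawal times.

Simulates a 16-day feeding study (pre-treatment day 0, 5 dosing days, 10
washout days; 6 pooled-egg replicates per group per day) for hens on
enrofloxacin-medicated feed, classifies every sample against the batch
positive control (spiked at 0.75x the validation level, 7.5 ug/kg for
both the parent drug and its metabolite ciprofloxacin), and reports how
many days after the end of treatment each residue stayed noncompliant.
"""

from eggscreen import group_timelines, load_panel, screen_study, study_fixture

panel = load_panel()
records, manifest = study_fixture("enrofloxacin", panel, seed=1)
calls = screen_study(records, manifest, panel)
timelines = group_timelines(calls, treatment_end_day=5)

for (group, analyte), days in sorted(timelines.items()):
    print(f"{group:8s} {analyte:14s} noncompliant for {days} day(s) after treatment end")

n_detected = sum(sc.call.compliance.value != "not_detected" for sc in calls)
print(f"{n_detected}/{len(calls)} sample/analyte calls had identifiable residues")
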