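"""Time-of-day weighting of daily EMA entries into behavior variables."""

from datetime import date

from phenosleep import EMAEntry, aggregate_participant, weighted_value

d = date(2023, 3, 6)
entries = [
    EMAEntry("p1", d, "caffeine", "afternoon", 2),            # 2 cups x 1.5
    EMAEntry("p1", d, "alcohol", "morning", 1),               # 1 drink x 1.5
    EMAEntry("p1", d, "stress", "before_bedtime", "severe"),  # code 3 x 2
    EMAEntry("p1", d, "nap", "afternoon", "2-3h"),            # code 2 x 1.5
]
for e in entries:
    print(f"{e.kind:9s} {e.slot:15s} {e.magnitude!s:8s} -> {weighted_value(e)}")
# Later-day caffeine/naps/stress are weighted more heavily; for alcohol
# the morning carries the higher weight (morning drinking is the more
# harmful pattern), with before-bedtime weighted highest of all.

totals = aggregate_participant(entries, study_days=28)
print("per-kind study totals:", totals)
# Summed over the 4-week study window; days without an entry add 0.
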