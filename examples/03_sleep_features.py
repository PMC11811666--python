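"""Per-night sleep parameters and the 4-week participant summary."""

from datetime import date, timedelta

from phenosleep import SleepNight, sleep_quality, summarize_participant, total_sleep_time

nights = [
    SleepNight("p1", date(2023, 3, 6) + timedelta(days=i),
               total_inactive_min=445 + 5 * (i % 3), total_awake_min=70 - 2 * (i % 3),
               rem_min=205, light_min=78, deep_min=54, n_wakeups=4)
    for i in range(28)
]
first = nights[0]
tst = total_sleep_time(first)
print(f"night 1: TST = {tst:.0f} min, quality = {sleep_quality(tst, first.total_awake_min):.1f}%")
# TST is the inactive period minus awake time; quality is the percent of
# the inactive period actually asleep — ~84% here, the scale a consumer
# wearable typically reports.

summary = summarize_participant(nights)
print(f"4-week means: TST {summary.tst_min:.1f} min, awake {summary.awake_min:.1f} min, "
      f"quality {summary.sleep_quality_pct:.1f}%, "
      f"wake-ups {summary.wakeups_per_week:.1f}/week over {summary.n_nights} nights")
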