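"""End-to-end study: simulate a cohort, extract features, compare the 4 groups.

Reproduces the study's qualitative pattern: objective sleep does not
separate the ISI severity groups, while the psychological scales do.
"""

from phenosleep import CohortConfig, generate_cohort, pipeline

cfg = CohortConfig(n_participants=250, seed=1)
cohort = generate_cohort(cfg, streams=("questionnaires", "ema", "sleep"))

scored = pipeline.score_questionnaires(cohort.questionnaires)
ema_vars = pipeline.ema_features(cohort.ema, study_days=cfg.study_days)
sleep_vars = pipeline.sleep_features(cohort.sleep)

report = pipeline.run_group_analysis(scored, [ema_vars, sleep_vars])
print("group sizes:", report["groups"])

print(f"{'variable':24s} {'test':15s} {'P':>8s}  post hoc")
for row in report["report"]:
    if row["variable"] in ("tst_min", "awake_min", "rem_min", "sleep_quality_pct",
                           "DBAS_total", "STAI_S_total", "stress", "caffeine"):
        print(f"{row['variable']:24s} {row['test']:15s} {row['omnibus_p']:8.3g}  "
              f"{row['posthoc']}")
# Sleep-structure rows stay non-significant (the groups share one sleep
# distribution by design); DBAS/STAI-S/stress show strong severity
# gradients; caffeine stays null — the subjective-objective discrepancy.
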