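"""Score self-report instruments and band a participant by ISI severity."""

from phenosleep import Instrument, QuestionnaireResponse, classify_isi, score, screen_eligibility

# A participant endorsing moderate difficulty on every ISI item
isi = QuestionnaireResponse(Instrument.ISI, (2, 3, 2, 3, 2, 2, 2))
scored = score(isi)
print(f"ISI total: {scored.total}  ->  band: {scored.category}")
# total 16 falls in the 15-21 band: moderate clinical insomnia

print("screening outcome:", screen_eligibility(scored.total, weekly_symptom_days=4))
# ISI > 15 with >= 3 symptomatic days/week enters the insomnia arm

auditc = QuestionnaireResponse(Instrument.AUDIT_C, (2, 1, 1), respondent_sex="female")
print("AUDIT-C:", score(auditc).total, score(auditc).category)
# total 4 >= the female cutoff of 3 -> hazardous drinking pattern

brian = QuestionnaireResponse(Instrument.BRIAN, (2,) * 21)
print("BRIAN total (18 scored items):", score(brian).total)
# only the 18 rhythm-disturbance items count: 18 x 2 = 36

print("band boundaries:", [classify_isi(t) for t in (7, 8, 21, 22)])
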