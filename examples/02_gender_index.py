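"""Score the six-item labour-market gender index and dichotomise it.

Each item is coded toward femininity (fewer working hours, lower
equivalized income, a more female-dominated sector, lower education, more
caregiving, more chore time); the sum (0-16) is split into
masculine/feminine at the sample median.
"""

import genderpaths as gp

cohort = gp.generate_cohort(gp.GeneratorConfig(seed=1))
indexed = gp.build_index(cohort)  # appends item codes, total, dichotomy

share = indexed.groupby("sex")["gender_binary"].value_counts(normalize=True)
print(indexed[["sex", "gender_total", "gender_binary"]].head(6).to_string())
print(f"\ncutoff used (sample median of totals): {indexed.gender_cutoff_used.iloc[0]}")
print("\nfeminine share by sex:")
print(share.to_string())
# Sex and gender are related but far from identical: most women and few
# men score feminine, which is exactly why the two are analysed as
# separate exposures.
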