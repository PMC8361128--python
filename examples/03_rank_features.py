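"""Rank features by Mann-Whitney U separation between the two groups.

Prints the top of the ranking: the statistic, the two-sided p-value, and
which features best separate ADHD-positive from control subjects. The
p-values are raw (no multiple-testing correction), matching the
descriptive use of the ranking.
"""

import pupilscreen as ps

cfg = ps.scaled_demo_config(effect="strong", trials_per_subject=6, seed=1)
cohort, _ = ps.generate_cohort(cfg)
clean, _ = ps.preprocess_cohort(cohort)
fm = ps.build_feature_matrix(clean)

ranked = ps.rank_features(fm, ps.RankMethod.MANN_WHITNEY)
print(f"{'feature':32s} {'U':>8s} {'p-value':>10s}")
for name, stat, p in ranked.entries[:10]:
    print(f"{name:32s} {stat:8.1f} {p:10.2e}")

top9 = ps.select_top_k(ranked, 9)
print("\ntop-9 selection (as used per CV fold):", ", ".join(top9))
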