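"""Render the four figure families into ./figures_example/.

Group-mean line plots (size/velocity/acceleration), a box plot of the
pupil-size standard deviation annotated with its Mann-Whitney p-value, a
RadViz class-separability projection of the top-ranked features, and the
pooled nested-CV ROC curve.
"""

from pathlib import Path

import pupilscreen as ps
from pupilscreen import viz

out = Path("figures_example")
out.mkdir(exist_ok=True)

cfg = ps.GeneratorConfig(n_adhd=12, n_ctrl=12, trials_per_subject=5,
                         effect="strong", seed=3)
cohort, _ = ps.generate_cohort(cfg)
clean, _ = ps.preprocess_cohort(cohort)
fm = ps.build_feature_matrix(clean)

for kind in ("size", "velocity", "acceleration"):
    viz.group_mean_lineplot(clean, out / f"group_mean_{kind}.png", kind)

p = viz.feature_distribution_plot(fm, "size_std", out / "size_std_box.png",
                                  "box")
print(f"size_std box plot annotated with p = {p:.3g}")

ranked = ps.rank_features(fm)
proj = viz.radviz_plot(fm, out / "radviz.png", ranked.names[:15])
print(f"RadViz: {len(proj.points)} subjects on {len(proj.anchors)} anchors")

report = ps.nested_cv(fm, ps.ClassifierSpec("logistic_regression"),
                      k_select=9, repetitions=5, seed=0)
viz.roc_plot([report], out / "roc.png")
print(f"figures written to {out}/")
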