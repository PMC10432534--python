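"""Summarise and compare the cross-validated classifiers.

Reports mean balanced accuracy with t-based 95% confidence intervals per
variant, all pairwise two-sample t-tests, and a bar chart with CI error
bars (results/model_comparison.png).  The headline contrast is the
learned-feature CNN against the manual-feature SVM on the 12 base
features.

Run from the repository root:  python analysis/05_report.py
"""

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

import matmotion as mm

frame = pd.read_csv("results/fold_results.csv")
variants = list(dict.fromkeys(frame["variant"]))

rows, ba = [], {}
for name in variants:
    grp = frame[frame["variant"] == name]
    ba[name] = grp["BA"].to_numpy()
    mean, (lo, hi) = mm.summarize(ba[name])
    rows.append({"variant": name, "mean_BA": mean, "CI_low": lo, "CI_high": hi,
                 "mean_TPR": grp["TPR"].mean(), "mean_TNR": grp["TNR"].mean()})
    print(f"{name}: BA {100 * mean:.2f}% (CI 95% [{100 * lo:.2f}%, "
          f"{100 * hi:.2f}%]), TPR {100 * grp['TPR'].mean():.2f}%, "
          f"TNR {100 * grp['TNR'].mean():.2f}%")
summary = pd.DataFrame(rows)
summary.to_csv("results/summary.csv", index=False)

print("\npairwise comparisons (two-sample t-test):")
comps = []
for i in range(len(variants)):
    for j in range(i + 1, len(variants)):
        t, p = mm.compare_models(ba[variants[i]], ba[variants[j]])
        comps.append({"variant_a": variants[i], "variant_b": variants[j],
                      "t": t, "p": p})
        flag = "*" if p < 0.05 else " "
        print(f"  {variants[i]} vs {variants[j]}: t = {t:+.3f}, p = {p:.4f} {flag}")
pd.DataFrame(comps).to_csv("results/comparisons.csv", index=False)

fig, ax = plt.subplots(figsize=(6, 4))
err = [summary["mean_BA"] - summary["CI_low"], summary["CI_high"] - summary["mean_BA"]]
ax.bar(summary["variant"], 100 * summary["mean_BA"],
       yerr=[100 * e for e in err], capsize=4, color="#4878a8")
ax.set_ylabel("balanced accuracy (%)")
ax.set_ylim(50, 102)
ax.set_title("Classifier comparison, infant-grouped 5-fold CV")
fig.tight_layout()
fig.savefig("results/model_comparison.png", dpi=150)
print("\nwrote results/summary.csv, results/comparisons.csv, "
      "results/model_comparison.png")
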