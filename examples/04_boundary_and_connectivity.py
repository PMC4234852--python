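"""Opposing transferases: unstable boundaries and connectivity-driven switching.

Two antagonistic enzymes (methyl- and acetyltransferase with identical
kinetics, initiation sites at positions 5 and 45) compete for the array.
With efficient recruitment (RE = 2) they form a boundary whose position
wanders; adding 10 chromatin-interaction sites lets enzymes jump across and
the array commits to -- and switches between -- majority states.
"""

from nucspread import get_preset, run_ensemble
from nucspread.analysis import boundary_statistic, switching_summary

boundary = run_ensemble(get_preset("fig6d").config, 500.0, 20, seed=3)
table = boundary_statistic(boundary, window=10.0, window_starts=(0, 200, 400))
for t0, group in table.groupby("window_start"):
    mean = (group["delta"] * group["probability"]).sum()
    spread = group["delta"].max() - group["delta"].min()
    print(f"window {t0:3.0f}s: mean(total M - total A) = {mean:+5.1f}, spread {spread}")

for name, label in [("fig6c", "RE=0.5, no connectivity"),
                    ("fig6d", "RE=2,   no connectivity"),
                    ("fig7c_ii", "RE=0.5, 10 sites @ 0.1/s")]:
    ens = run_ensemble(get_preset(name).config, 500.0, 12, seed=5)
    s = switching_summary(ens)
    majority = (s["visited_m"] | s["visited_a"]).mean()
    print(f"{label}: {100 * majority:3.0f}% of runs reach a majority state "
          f"(majority-M {s['visited_m'].sum()}, majority-A {s['visited_a'].sum()})")

print(
    "\nThe RE=2 boundary drifts around zero (symmetric competition) but"
    "\nrarely lets either mark take over.  Weak recruitment without"
    "\nconnectivity barely modifies the array; with 10 interaction sites the"
    "\nsame weak enzymes drive nearly every run into a fully methylated OR"
    "\nfully acetylated state -- connectivity introduces bistability."
)
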