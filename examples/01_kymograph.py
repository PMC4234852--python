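"""A single diffusing methyltransferase writes a transient local pattern.

Simulates 200 s of the diffusion mechanism (enzyme influx only at the central
initiation site, position 25 of 50) and prints a coarse text kymograph:
one row per 10 s, one character per nucleosome (M methylated, A acetylated,
. unmodified, * methyltransferase-occupied).
"""

from nucspread import get_preset, simulate

preset = get_preset("fig2")
traj = simulate(preset.config, t_end=200.0, seed=1)
print(f"{traj.n_events} reactions fired in 200 s of model time\n")

kymo = traj.snapshot_matrix(10.0)
symbols = {0: ".", 1: "A", 2: "M"}
for r, t in enumerate(kymo.times):
    row = "".join(
        "*" if kymo.occ[r, i] else symbols[int(kymo.mods[r, i])]
        for i in range(kymo.mods.shape[1])
    )
    print(f"t={t:5.0f}s  {row}")

print(
    "\nMethylation stays confined near the initiation site (column 25) and"
    "\nturns over continuously: the diffusion mechanism alone produces a"
    "\nnarrow, dynamic peak, not a gene-wide pattern."
)
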