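"""Where the rate constants come from.

Every kinetic parameter of the model is derived from measured biophysical
quantities rather than fitted: Smoluchowski diffusion-limited association
for binding and background modification, the 1D sliding diffusion
coefficient for the hop rate, and the FRAP residence time for dissociation.
"""

from nucspread.physical import (
    PhysicalConstants,
    recruitment_efficiency,
    table1_report,
)

pc = PhysicalConstants()  # 5000 enzymes, 500 um^3 nucleus, D_E = 3.8 um^2/s, ...
print("derived rate constants (s^-1):")
for name, value in table1_report(pc).items():
    print(f"  {name:26s} {value:8.3f}")

print("\nrecruitment efficiency RE = k_recruitment / k_demodification:")
for k_rec in (0.24, 0.48, 1.2, 2.4, 4.8):
    print(f"  k_recruitment = {k_rec:4.2f}/s  ->  RE = {recruitment_efficiency(k_rec, 2.4):.2f}")

print(
    "\nk_on ~ 2.4/s is the apparent first-order rate at which any of the"
    "\n5000 nuclear enzymes finds a 5 nm DNA site; the same value serves as"
    "\nthe ubiquitous demodification and background-acetylation rate."
    "\nk_slide = 2 D / d^2 ~ 0.6/s converts the measured on-chromatin 1D"
    "\ndiffusion coefficient into a nucleosome-to-nucleosome hop rate."
)
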