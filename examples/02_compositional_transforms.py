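"""Compositional handling of mud/sand/gravel fractions.

Shows zero replacement at the 1e-4 detection level, the base-10 additive
log-ratio (ALR) transform and its closed-form inverse, and the Long/Folk
four-class substrate classification.
"""

import numpy as np

from sedmap import composition

grabs = np.array(
    [
        [0.70, 0.28, 0.02],   # muddy site
        [0.02, 0.95, 0.03],   # sandy site
        [0.30, 0.60, 0.10],   # mixed site
        [0.05, 0.45, 0.50],   # coarse site
        [0.00, 0.93, 0.07],   # mud below detection -> exact zero
    ]
)

closed = composition.replace_zeros(grabs)
alr = composition.alr_forward(closed)
back = composition.alr_backward(alr)
codes = composition.classify(grabs)

print(f"{'mud':>6}{'sand':>6}{'grav':>6} | {'ALR_ms':>8}{'ALR_gs':>8} | class")
for c, a, code in zip(grabs, alr, codes):
    print(f"{c[0]:>6.2f}{c[1]:>6.2f}{c[2]:>6.2f} | {a[0]:>8.3f}{a[1]:>8.3f} | "
          f"{composition.class_name(code)}")

print(f"\nround-trip error after zero replacement: "
      f"{np.abs(back - closed).max():.2e}")
print("ALR_ms = log10(mud/sand), ALR_gs = log10(gravel/sand); the inverse "
      "recovers closed fractions exactly, so maps built from modelled ALR "
      "values always sum to 1.")
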