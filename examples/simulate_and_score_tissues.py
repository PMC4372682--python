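"""Simulate tail/striatum/liver traces and recover the tissue ordering.

Generates eight traces per tissue from the calibrated default profiles,
scores each, and prints per-tissue mean indices: tail is stable (~0),
striatum shows a broad expansion tail (~8) and liver a distinct expanded
mode (~12), matching the characteristic somatic-instability hierarchy of
5-month knock-in mice.
"""

import numpy as np

from cagscore import default_profile, instability_index, simulate_trace, true_index

for kind in ("tail", "striatum", "liver"):
    profile = default_profile(kind)
    indices = [
        instability_index(simulate_trace(profile, seed=s)).instability_index
        for s in range(8)
    ]
    print(
        f"{kind:9s} mean index {np.mean(indices):+6.2f} "
        f"(SD {np.std(indices, ddof=1):.2f}, generating expectation "
        f"{true_index(profile):+6.2f})"
    )

# Each index is in CAG repeat units: the mean repeat-length change of the
# retained peak mass relative to the main allele.  The generating
# expectation is the noise-free value implied by each tissue profile.
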