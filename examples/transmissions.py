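"""Simulate paternal transmissions and summarise the expansion bias.

Generates intergenerational transmissions of a 139-CAG paternal allele
with a 74% expansion probability, then reports the observed bias and the
per-cross mean +/- SD of the signed repeat-length change.
"""

from cagscore import delta_summary, expansion_bias, simulate_transmissions

events = simulate_transmissions(
    n=50, p_expand=0.74, magnitude_sd=3.0, seed=1, parent_cag=139, cross="host"
)

print(f"transmissions: {len(events)}")
print(f"expansion bias: {expansion_bias(events):.1f}% of offspring repeats longer")
print(delta_summary(events).to_string(index=False))

# The bias is the fraction of transmissions with a positive repeat-length
# change; the summary gives the mean signed change in CAG units per cross.
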