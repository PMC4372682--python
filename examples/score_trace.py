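"""Score one electropherogram peak ladder by hand.

Builds a small liver-like trace (constitutive allele at 139 CAG plus a
somatically expanded population near 152), applies the 20% peak filter and
prints the instability/expansion/contraction indices and the mosaicism
pattern metrics.
"""

from cagscore import RepeatTrace, distance_between_modes, instability_index

trace = RepeatTrace(
    peaks={137: 180.0, 138: 420.0, 139: 1000.0, 151: 350.0, 152: 800.0, 153: 400.0},
    sample_id="demo",
    tissue="liver",
    constitutive_cag=139,
)

result = instability_index(trace, rel_threshold=0.20)
pattern = distance_between_modes(trace, rel_threshold=0.20)

print(f"main allele:        {result.main_allele_cag} CAG")
print(f"instability index:  {result.instability_index:+.3f}")
print(f"  expansion index:  {result.expansion_index:+.3f}")
print(f"  contraction index:{result.contraction_index:+.3f}")
print(f"retained peaks:     {sorted(result.retained_peaks)}")
print(f"modes:              {pattern.modes}")
print(f"distance between modes: {pattern.distance_between_modes} CAG")
print(f"distance to longest:    {pattern.distance_to_longest} CAG")

# The instability index is the height-weighted mean CAG change relative to
# the main allele over peaks at >= 20% of its height: positive values mean
# net somatic expansion.  The two modes ~13 repeats apart are the bimodal
# pattern typical of liver mosaicism.
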