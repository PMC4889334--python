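"""The nascent-chain intensity model: from ribosome positions to fluorescence.

A ribosome at codon x has exposed only the epitopes synthesized more than an
exit-tunnel offset ago, so its nascent chain carries a fraction f(x) of the
full label.  Site intensity is the sum of f over all ribosomes; dividing by
the positional mean c_bar converts intensity to a ribosome count.
"""

import ribotrace as rt

c = rt.get_preset("kif18b_suntag24")
print(f"reporter: {c.name}, L = {c.orf_length_codons} codons, "
      f"{c.n_epitopes} epitopes, exit tunnel {c.exit_tunnel_codons} codons")

for x in (0, 61, 374, 669, 1467):
    print(f"  f({x:4d}) = {rt.exposed_epitope_fraction(x, c):.3f}")

cbar = rt.mean_positional_correction(c)
print(f"mean positional correction c_bar = {cbar:.3f}")
print(f"site with ribosomes at 374 and 1467 -> intensity "
      f"{rt.site_intensity([374, 1467], c):.2f} mature-protein units")

I = 7.52
print(f"intensity {I} units -> {rt.estimate_ribosome_count(I, c):.1f} ribosomes")

full = rt.expected_label_ratio(rt.LabelStoichiometry(occupancy=1.0))
half = rt.expected_label_ratio(rt.LabelStoichiometry(occupancy=0.5))
print(f"mRNA label vs single protein: {full:.0f}-fold at full occupancy, "
      f"{half:.0f}-fold at 50% occupancy")
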