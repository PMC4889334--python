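"""Initiation heterogeneity: a repressive 5' UTR with a bright escaper minority.

Most transcripts carrying the repressive leader are silent, a minority
translate weakly, and a few percent escape repression entirely.  The
ribosome-weighted view shows that this tiny bright fraction carries about
half of all translating ribosomes.
"""

import numpy as np

import ribotrace as rt
from ribotrace.estimators import intensity_distribution

cfg = rt.ScenarioConfig("emi1_mixture", n_mrna=400, seed=40,
                        construct="emi1_long_5utr")
ds = rt.generate_dataset(cfg)
vals = np.array([tr.green[-5:].mean() for tr in ds.traces])

thr = 2 * cfg.noise_sigma0  # translating cutoff: 2 background SDs
d = intensity_distribution(vals, [0.0, 4.0, 200.0], translating_threshold=thr)
print(f"{cfg.n_mrna} mRNAs; translating fraction "
      f"{d.translating_fraction*100:.0f}% (silent majority ~80%)")
row = d.table.loc[1]
print(f"bright bin (> 4 units): {row['mrna_fraction']*100:.1f}% of translating "
      f"mRNAs, carrying {row['intensity_fraction']*100:.0f}% of the summed "
      f"ribosome signal")
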