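"""Simulated qPCR induction analysis with the linker-length correlation.

Simulates a replicate Ct experiment in which the four dyad-bearing AUX/IAA
genes are induced with strength decreasing as their linker lengthens
(linkers 0, 1, 4, 12 nt) while the two motif-free genes stay at 1x, then
runs the comparative-threshold-cycle quantification, joins the dyad calls
and computes the Spearman correlation of fold change against linker
length.  Expected output: recovered fold changes near the simulated truth,
stars for the induced genes, motif_present=False for StIAA4/5, and a
negative rank correlation.
"""

import pandas as pd

import beldyad as bd
from beldyad.elements import AUX_IAA_ELEMENTS, INDUCED_AUX_IAA, element_dyads

by_number = {e.number: e for e in AUX_IAA_ELEMENTS}
linkers = {
    gene: element_dyads(by_number[num].element)[0].linker_length
    for gene, num in INDUCED_AUX_IAA.items()
}
true_fc = {"StIAA3": 8.0, "StIAA14": 5.0, "StIAA22": 3.5, "StIAA24": 2.0}

spec = bd.QpcrSimSpec(
    genes=tuple(true_fc) + ("StIAA4", "StIAA5"),
    true_fold_change=true_fc,
    n_replicates=3,
    ct_noise_sd=0.3,
    seed=2013,
)
results = bd.fold_change_table(bd.simulate_ct_table(spec))

scan_df = pd.DataFrame(
    [
        {"gene_id": g, "orientation": element_dyads(by_number[n].element)[0].orientation,
         "linker_length": linkers[g]}
        for g, n in INDUCED_AUX_IAA.items()
    ]
)
report = bd.induction_report(scan_df, results)
print(report.to_string(index=False))

rho, p = bd.linker_induction_correlation(
    [r for r in results if r.gene in linkers], linkers
)
print(f"\nSpearman fold-change vs linker length: rho = {rho:+.2f} (p = {p:.3f})")
print("negative rho: induction weakens as the dyad linker lengthens.")
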