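"""Partitioning of two analgesics between the phases of a PEG600 + KOH system.

K is the top/bottom drug ratio; EE% = 100*K/(K+1) is the fraction recovered
in the polymer-rich phase.  ln K is correlated with the polymer composition
difference across the tie-line via the Diamond-Hsu relation and its
three-parameter extension.
"""

from atpskit import fit_diamond_hsu, fit_modified_diamond_hsu, \
    match_records_to_tielines, rank_drugs_by_hydrophobicity
from atpskit.datasets import load_peg600_koh_partition, load_peg600_koh_tielines

tielines = load_peg600_koh_tielines()
records = match_records_to_tielines(load_peg600_koh_partition(), tielines)

for drug in ("ibuprofen", "acetaminophen"):
    recs = [r for r in records if r.drug == drug]
    dh = fit_diamond_hsu(recs)
    mdh = fit_modified_diamond_hsu(recs)
    print(f"{drug}:")
    for r in recs:
        print(f"  dw(PEG)={r.delta_w_peg:5.2f} wt%   K={r.K:6.2f}   EE={r.EE:6.2f}%")
    print(f"  Diamond-Hsu         A={dh.A:.5f}, B={dh.B:.2e}  (sd {dh.fit.sd:.4f} on ln K)")
    print(f"  modified (3-param)  A1={mdh.A1:.3f}, B1={mdh.B1:.4f}, C1={mdh.C1:.2e}"
          f"  (sd {mdh.fit.sd:.4f})")

ranking = rank_drugs_by_hydrophobicity(
    records, {"ibuprofen": 3.97, "acetaminophen": 2.34}
)
print()
print(f"EE ordering: {' > '.join(ranking['ee_order'])}; "
      f"log Kow ordering: {' > '.join(ranking['log_kow_order'])}; "
      f"consistent: {ranking['consistent']}")
print()
print("The more hydrophobic drug (higher log Kow) favours the less polar,")
print("polymer-rich top phase at every composition, and the extra intercept of")
print("the modified correlation always lowers the residual sd (nested models).")
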