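"""Charge bookkeeping and product metrics for an electrolysis run.

A 10-hour electrolysis at 5 mA passes 180 C.  If half of that charge made
dihydroxyacetone (a 2-electron product) in 0.1 L of electrolyte, the DHA
concentration is Q·s/(q·F·V) = 4.66 mM — and running the bookkeeping
backwards returns the 50% Faradaic efficiency we started from.
"""

import chromsolve as cs

q_total = cs.total_charge(5e-3, 10 * 3600)
print(f"total charge: {q_total:.0f} C")

conc = cs.concentration_from_charge(q_total, selectivity=0.5, q=2,
                                    volume_l=0.1)
print(f"DHA at 50% selectivity in 0.1 L: {conc:.3g} mM")

n_mol = conc * 1e-3 * 0.1
fe = cs.faradaic_efficiency(n_mol, 2, q_total)
print(f"Faradaic efficiency recomputed from that concentration: {fe:.1f}%")

record = cs.ElectrolysisRecord(q_total=q_total, volume_l=0.1)
print()
print(cs.pecmetrics.format_pec_report({"DHA": conc, "FA": 1.0}, record))
print("\nFE_total is the share of the passed charge the quantified "
      "products account for; above 100% it flags a quantification error.")
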