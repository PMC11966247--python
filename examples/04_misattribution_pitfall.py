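"""How overlooking peak overlap skews selectivities.

The merged peak near 13.8 min contains both glycerol and DHA.  If it is
attributed entirely to DHA — and the co-eluting product GCAD is missed —
the apparent concentrations are 1.34 mM DHA, 0.77 mM FA, 0.42 mM GLAD, and
the relative selectivities look plausible (DHA dominant at 53%), hiding the
error.  The Faradaic-efficiency total is the safeguard: correctly
quantified product sets keep FE_total at or below 100%.
"""

import chromsolve as cs

apparent = {"DHA": 1.34, "FA": 0.77, "GLAD": 0.42}
rs = cs.relative_selectivity(apparent)
print("apparent selectivities when the overlap is overlooked:")
for name, pct in rs.items():
    print(f"  {name}: {pct:.1f}%")

# inflate DHA far enough and the electron bookkeeping exposes the mistake
record = cs.ElectrolysisRecord(q_total=1.0, volume_l=0.1)
print()
print(cs.pecmetrics.format_pec_report({"DHA": 10.0}, record))
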