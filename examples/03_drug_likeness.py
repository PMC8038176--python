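"""Drug-likeness filter panel on named screening hits.

Violation counts per rule family: P = PAINS alerts, L = Lipinski
(rule-of-five, MLOGP variant), V = Veber, E = Egan. A clean compound has
total 0.
"""

from dascreen.compounds import NAMED_HITS
from dascreen.filters import filter_panel, reports_to_frame

reports = filter_panel(NAMED_HITS)
print(reports_to_frame(reports).to_string(index=False))
print(f"{sum(r.clean for r in reports)}/{len(reports)} compounds clean")

# (S)-crizotinib passes everything; quinestrol carries one Lipinski
# violation (Moriguchi logP 5.11 > 4.15 — a lipophilic steroid ether).
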