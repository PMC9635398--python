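"""Sequence developability of a designed Fv.

Three sequence-level liabilities with their windowing conventions:
instability index on the full heavy chain (> 40 flags instability),
GRAVY on the designed region padded ±10 residues (positive = hydrophobic),
and Henderson–Hasselbalch net charge of the full Fv at pH 7.
"""

import fvdesign as fd
from fvdesign.developability import developability_report

heavy = "EVQLVESGGGLVQPGGSLRLSCAASGFNIK"
light = "DIQMTQSPSSLSASVGDRVTITCRASQ"
fv = fd.concatenate_fv(heavy, light, fd.default_numbering(heavy, light))
region = fd.make_design_region(fv, ["H25", "H26", "H27", "H28"])

report = developability_report(fv, region)
print(f"heavy chain ({len(heavy)} aa), designed H25-H28")
print(f"instability index (full heavy chain): {report.instability_index:.2f}")
print(f"GRAVY (design region ±10 residues):   {report.gravy:.3f}")
print(f"net charge (full Fv, pH 7.0):         {report.net_charge:+.3f}")
print("These are screening heuristics: II above 40 flags potential")
print("instability (this truncated toy fragment scores high), a positive")
print("GRAVY leans hydrophobic, and the net charge is near neutral.")
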