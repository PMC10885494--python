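"""Tour of the slippery-site motif catalog.

Classifies a few 7-nt windows (each ending at the ribosome's P-site codon
boundary) and prints every class with its template and the probability that
a random window matches it -- the precedence order when templates overlap:
a window that is both *six* and *threethree* is reported as the rarer *six*.
"""

from prfscan import MOTIF_CLASSES, classify_window, random_probability

for window in ("GGGGGAA", "CCCGGAA", "CAAAAAA", "AAGGGGG", "ACGTACG"):
    m = classify_window(window)
    print(f"{window} -> {m.name if m else 'no motif'}")

print()
print(f"{'class':<12} {'dir':>4} {'template':<10} {'P(random)':>10}")
for m in sorted(MOTIF_CLASSES, key=random_probability):
    runs = "-".join(str(r) for r in m.runs)
    print(f"{m.name:<12} {m.direction:>+4} {runs:<10} {random_probability(m):>10.2e}")
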