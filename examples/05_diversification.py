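"""Net diversification rates for a recent radiation.

A clade of ~39 species whose crown age lies between 1.4 and 3.6 My gives
method-of-moments net diversification rates of roughly 0.8-2.1 species/My
(extinction-free), on par with celebrated radiations in wetter biomes.
"""

from radphylo.diversification import DiversificationInput, net_diversification

for t in (3.6, 1.4):
    r = net_diversification(DiversificationInput(39, t, "crown", 0.0))
    print(f"crown age {t} My, 39 species, eps=0   -> {r:.2f} species/My")

print()
print("sensitivity to relative extinction (crown age 3.6 My):")
for eps in (0.0, 0.5, 0.9):
    r = net_diversification(DiversificationInput(39, 3.6, "crown", eps))
    print(f"  eps={eps:.1f} -> {r:.3f} species/My")
print("  -> higher assumed extinction lowers the inferred net rate; the")
print("     printed range corresponds to the extinction-free estimator")
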