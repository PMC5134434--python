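"""Fourier-descriptor shape features of a regular vs a misshapen fruit.

Generates one smooth ovoid and one fruit with a 7 mm surface lobe, computes
the six shape features from each top-view silhouette, and shows how the
harmonic sums S1-S3 react to the deformation.
"""

from mangograde.shape_features import features_from_mask
from mangograde.synthetic_scene import FruitSpec, Lobe, generate_fruit

regular = generate_fruit(FruitSpec())
misshapen = generate_fruit(
    FruitSpec(lobes=(Lobe(position=0.3, amplitude_mm=7.0, width=0.12),))
)

print(f"{'feature':12} {'regular':>10} {'misshapen':>10}")
fr = features_from_mask(regular.top_mask).as_dict()
fm = features_from_mask(misshapen.top_mask).as_dict()
for name in fr:
    print(f"{name:12} {fr[name]:10.2f} {fm[name]:10.2f}")

print("\nS1-S3 weight the boundary spectrum by m, m^2, m^3: the lobe adds")
print("high-frequency content, so S3 grows the fastest — the separation the")
print("regular/misshapen discriminant exploits. Aspect ratio and roundness")
print("barely move: the lobe is local, not a change of overall proportions.")
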