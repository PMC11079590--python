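"""Colocalization of two traits over an LD-correlated region.

Simulates a 100-variant region twice: once with a single causal variant
shared by both traits, once with two distinct causal variants in modest
LD (r ~ 0.2).  The five-hypothesis posteriors should put their mass on
H4 (shared variant) in the first case and on H3 (distinct variants) in
the second.
"""

from protmr import RegionConfig, coloc_abf, simulate_coloc_region

shared1, shared2, _ = simulate_coloc_region(RegionConfig(seed=5))
res = coloc_abf(shared1, shared2)
print("shared causal variant:")
for h, pp in enumerate(res.pp):
    print(f"  PP.H{h} = {pp:.4f}")
print(f"  colocalization call (PP.H4 > 0.70): {res.h4_significant}")

d1, d2, _ = simulate_coloc_region(
    RegionConfig(causal_index_1=42, causal_index_2=58, seed=5)
)
res_d = coloc_abf(d1, d2)
print("\ndistinct causal variants (LD r ~ 0.2):")
for h, pp in enumerate(res_d.pp):
    print(f"  PP.H{h} = {pp:.4f}")
print(f"  colocalization call: {res_d.h4_significant}")

print("\nH4 mass means the two traits track one shared causal variant; H3")
print("mass means two different variants in LD, i.e. the MR signal could be")
print("confounded by linkage rather than reflecting a shared mechanism.")
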