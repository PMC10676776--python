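"""GC-decile histograms and Z-space cosine similarity of sequence sets.

Origin-like, uniform-random and genome-like sets occupy different GC
deciles (L_i = GC in (10(i-1)%, 10i%]), and in the 252-dimension Z-space
the origin-like set coheres with itself far more than with background —
the geometric signal the classifier exploits.
"""

import oriforge as of

n, lr = 150, (300, 1500)
sets = {
    "ori": of.gen_ori_like(n, lr, seed=1),
    "random": of.gen_uniform_random(n, lr, seed=2),
    "genome": of.gen_genome_like(n, lr, seed=3),
}

print("GC decile counts (L1..L10):")
for name, seqs in sets.items():
    hist = of.gc_histogram(seqs)
    print(f"  {name:>6}: {hist.bin_counts}")

config = of.ZSpaceConfig()
encoded = {name: list(of.encode_batch(seqs, config)) for name, seqs in sets.items()}
sim = of.mean_set_similarity(encoded)
print("\nmean pairwise cosine similarity (1=parallel, 0=unrelated):")
header = "        " + "".join(f"{l:>8}" for l in sim.labels)
print(header)
for label, row in zip(sim.labels, sim.values):
    print(f"  {label:>6}" + "".join(f"{v:>8.3f}" for v in row))
print("\nwithin-set values exceed cross-set values: each set clusters,")
print("and origins sit apart from both backgrounds in Z-space.")
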