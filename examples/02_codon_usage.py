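"""Codon-usage indices of one gene and codon preference across a cohort.

Computes RSCU, ENC and the GC-site contents for MT-CYB of one synthetic
genome, then classifies codons as over-represented (mean RSCU > 1.6) or
preferred (1.0 < mean RSCU <= 1.6) across five taxa with a planted
A/C-ending bias, recovering the planted preference.
"""

import mitocub as mc
from mitocub.codon_usage import extract_codons, mean_rscu_and_classify, profile

record, _ = mc.generate_mitogenome(mc.GeneratorConfig(seed=2))
gene = next(g for g in mc.extract_pcgs(record) if g.gene == "MT-CYB")
counts = extract_codons(gene.cds, gene=gene.gene, taxon=gene.taxon)
p = profile(counts, strand_label=gene.strand_label)

print(f"{p.gene} ({p.n_codons} codons, {p.strand_label}-strand)")
print(f"  ENC  = {p.enc:.2f}   (20 = maximal bias, 60 = uniform usage)")
print(f"  GC12 = {p.gc12:.3f}  GC3 = {p.gc3:.3f}  GC3s = {p.gc3s:.3f}")
print(f"  RSCU(CTA) = {p.rscu['CTA']:.2f}  RSCU(CTG) = {p.rscu['CTG']:.2f}")
print()

profiles = []
for seed in range(5):
    c, _ = mc.generate_codon_counts(3000, seed=seed, ac_tilt=3.0)
    c.taxon = f"taxon_{seed}"
    profiles.append(profile(c, strand_label="L"))
cls, mean_rscu, tallies = mean_rscu_and_classify(profiles)
over = sorted(c for c, lab in cls.items() if lab == "over_represented")
ac = sum(1 for c in over if c[2] in "AC")
print(f"over-represented codons across 5 taxa: {len(over)}, "
      f"{ac} of them A/C-ending: {' '.join(over)}")
print("A strong A/C third-position preference marks light-strand genes;")
print("the classifier recovers the tilt the generator planted.")
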