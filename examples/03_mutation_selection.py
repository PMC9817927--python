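"""Mutation pressure vs selection: PR2, ENC-GC3s curve, neutrality plot.

Builds a 10-taxon synthetic cohort and runs the three codon-usage-bias
diagnostics.  PR2 points away from (0.5, 0.5) show strand-asymmetric
pressure; ENC below Wright's expected curve shows bias beyond what GC3s
explains; a neutrality slope far below 1 shows selective constraint on
codon positions 1+2.
"""

import mitocub as mc
from mitocub import pipeline
from mitocub.bias_analysis import pr2_point
from mitocub.codon_usage import extract_codons

records, _ = mc.generate_cohort(mc.GeneratorConfig(seed=3, n_taxa=10))
profiles = pipeline.profiles_for_cohort(records)

g = next(g for g in mc.extract_pcgs(records[0]) if g.gene == "MT-ND2")
pt = pr2_point(extract_codons(g.cds, gene=g.gene, taxon=g.taxon))
print(f"PR2 for {g.gene} ({g.strand_label}-strand): "
      f"GC-bias {pt.gc_bias:.3f}, AT-bias {pt.at_bias:.3f} -> quadrant {pt.quadrant}")
print("  (< 0.5, > 0.5) means C over G and A over T at third positions.")
print()

_, curve_summary, fits = pipeline.bias_report(profiles)
print(f"ENC-GC3s: {curve_summary['fraction_below_curve']:.0%} of "
      f"{curve_summary['n_points']} gene/taxon points fall below the expected curve.")
print()

# a planted neutrality relation recovered by the per-gene regression
gc3, gc12, _ = mc.generate_neutrality_points(slope=0.1364, intercept=0.35,
                                             noise_sd=0.005, n=22, seed=4)
fit = mc.neutrality_fit(gc3, gc12, gene="MT-ND5")
print(f"neutrality fit: slope {fit.slope:.4f} (r2 {fit.r2:.2f}) -> mutation "
      f"pressure contributes {fit.mutation_contribution_pct:.2f}%")
print("A slope this far below 0.5 marks selection as the dominant force.")
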