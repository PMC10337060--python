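"""Compartment-level program enrichment in synthetic bulk profiles.

Generates 10 patients x 5 surgical compartments (Core, Rim, invasive
margin, 5ALA+, 5ALA-), contrasts the 5ALA+ fraction against everything
else with a per-gene Welch t-test, and runs preranked GSEA over the ten
planted transcriptional programs.
"""

from margin_profiler import enrichment, synthetic

em, ann, programs = synthetic.generate_bulk_regions(seed=0)
log = em.to_log2()
ala = ann.index[ann["compartment"] == "5ALA_pos"].tolist()
rest = ann.index[ann["compartment"] != "5ALA_pos"].tolist()

de = enrichment.differential_expression(log, ala, rest)
ranked = enrichment.RankedList.from_stats(de["t"].fillna(0.0))
results = enrichment.gsea_preranked(ranked, programs, n_perm=1000, seed=0)

print(f"{'program':<14}{'NES':>7}{'padj':>9}  leading edge")
for r in sorted(results, key=lambda r: -r.nes):
    print(f"{r.set_name:<14}{r.nes:>7.2f}{r.padj:>9.4f}  {len(r.leading_edge)}/{r.size} genes")
print()
print("Positive NES marks programs planted as active in 5ALA+ cells (MES,")
print("InfWound, GPM, MTC, TNF, InfResponse); negative NES marks programs")
print("planted elsewhere (Core hypoxia/stemness, Rim proliferation, neuronal background).")
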