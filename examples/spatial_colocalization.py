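"""Spatial co-localization and segmentation on the planted 32x33 spot grid.

Scores every spot for the planted programs with ssGSEA, measures local
(geographically weighted) correlation between the 5ALA signature and the
immune-reactive program, contrasts chr7/chr10 copy number between the
top-50 5ALA spots and non-tumor spots, and segments enriched spots into
tumor-interior (ENR_CT) versus invasive-margin (ENR_INV) classes.
"""

import numpy as np

from margin_profiler import cnv, spatial, synthetic

grid, programs, positions = synthetic.generate_spatial_grid(seed=0)
spatial.score_spots(grid, programs, method="ssgsea")

# local co-localization of the 5ALA and immune channels
local = spatial.gw_correlation(grid, "ALA_SIG", "IMMUNE", bandwidth=5, kernel="gaussian")
niche = list(grid.masks["ala_inv"] | grid.masks["ala_ct"])
inside = local.rho[niche].median()
outside = local.rho[~local.rho.index.isin(niche)].median()
print(f"median local rho inside 5ALA niche {inside:.2f} vs outside {outside:.2f}")

# chr7/chr10 contrast: top-50 5ALA spots vs 50 non-tumor spots
reference = (grid.channels["PROLIF"] + grid.channels["ALA_SIG"]).nsmallest(200).index
profile = cnv.infer_cnv(grid.expression.to_log2(), positions, list(reference), window=51)
contrast = cnv.spot_cnv_contrast(grid, profile, "ALA_SIG", nt_mask=grid.masks["nt"], k=50)
for chrom, row in contrast.iterrows():
    print(f"{chrom}: mean difference {row['mean_diff']:+.2f}, p = {row['pval']:.2e}")

# segmentation into 5ALA-CT vs 5ALA-INV
calls = cnv.call_ploidy(profile, tau=0.35)
ct_mask = set(calls.calls.index[calls.calls["chr7_mean"] >= 0.35])
seg = spatial.segment_enriched_spots(grid, "ALA_SIG", ct_mask=ct_mask)
counts = seg.labels.value_counts()
print(f"segmentation: {counts.get('ENR_CT', 0)} ENR_CT, {counts.get('ENR_INV', 0)} ENR_INV "
      f"(threshold {seg.threshold:.3f})")
print()
print("Co-localization is planted only inside the 5ALA niches; the enriched")
print("spots split into a tumor-interior pocket and an invasive-margin arc")
print("carrying the Chr7-gain/Chr10-loss tumor karyotype at reduced purity.")
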