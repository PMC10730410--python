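"""Build a brain-regulatory eQTL test set from catalog, peaks and loops.

Filters the eQTL catalog at FDR < 0.05 per brain region, intersects the
chromatin-accessibility peak union with Hi-C loop-anchor territory, and
keeps the candidate variants that fall inside the intersection. Prints the
survival counts: every planted eQTL is significant somewhere, and the
regulatory restriction drops those not covered by both evidence layers.
"""

import regeqtl as rq
from regeqtl.regulatory import accessibility_union

config = rq.demo_config()
cohort = rq.simulate_cohort(config)
catalog = rq.simulate_eqtl_catalog(config)
peaks, loops = rq.simulate_regulatory_tracks(config, cohort)

rows, candidates = rq.filter_significant_eqtls(catalog, known_regions=rq.BRAIN_REGIONS)
print(f"catalog rows: {len(catalog)}  significant rows (FDR<0.05): {len(rows)}")
print(f"deduplicated candidate variants: {len(candidates)}")

access = accessibility_union(peaks.values())
regulatory = rq.build_regulatory_regions(peaks.values(), loops)
print(f"accessibility union: {len(access)} intervals, {access.total_bases:,} bp")
print(f"accessibility ∩ loop anchors: {len(regulatory)} intervals, "
      f"{regulatory.total_bases:,} bp")

selected, funnel = rq.select_regulatory_eqtls(
    candidates, regulatory, accessibility=access
)
print(f"\nfunnel: {funnel.significant} significant -> "
      f"{funnel.in_accessibility} in accessible chromatin -> "
      f"{funnel.in_regulatory} in regulatory territory (test set)")
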