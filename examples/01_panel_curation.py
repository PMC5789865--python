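"""Curate a disease panel: inclusion gates, ancestry transfer, LD pruning.

Walks one toy endometrial-cancer panel through the three curation stages a
literature-derived marker list must survive before it can be scored.
"""

import numpy as np

from poprisk import (DiseasePanel, SnpMarker, filter_by_discovery_criteria,
                     ld_prune, transform_panel)


def marker(rsid, orx, p, study="gwas_discovery", **kw):
    return SnpMarker(rsid=rsid, risk_allele="G", other_allele="A",
                     or_per_allele=orx, p_discovery=p, study_type=study,
                     n_cases=3000, n_controls=3000, **kw)


# --- Stage 1: inclusion gates -------------------------------------------------
candidates = [
    marker("rs_strong", 1.4, 3e-9),                      # clears genome-wide gate
    marker("rs_borderline", 1.3, 5e-7),                  # misses 1e-7 gate
    marker("rs_replicated", 1.2, 5e-7, "gwas_with_replication",
           p_replication=0.01),                           # rescued by replication
    marker("rs_candidate", 1.6, 0.02, "candidate_snp"),   # nominal gate suffices
]
kept = filter_by_discovery_criteria(candidates)
print("inclusion gates (strict P < 1e-7 / 1e-6+replication / 0.05):")
print(f"  {len(candidates)} candidates -> {len(kept)} kept:",
      [m.rsid for m in kept])

relaxed = filter_by_discovery_criteria(candidates, endometrial_exception=True)
print("with the endometrial exception (gate relaxed to 1e-5):")
print(f"  {len(relaxed)} kept — rs_borderline now clears:",
      [m.rsid for m in relaxed])

# --- Stage 2: transfer a European-discovery panel to an East-Asian cohort ----
panel = DiseasePanel("endometrial_cancer", [
    marker("rs_strong", 1.4, 3e-9, east_asian_status="validated"),
    marker("rs_replicated", 1.2, 5e-7, "gwas_with_replication",
           p_replication=0.01, east_asian_status="tested_null"),
    marker("rs_candidate", 1.6, 0.02, "candidate_snp",
           east_asian_status="untested"),
])
ea_entries = [
    marker("rs_strong", 1.25, 3e-9, east_asian_status="validated",
           discovery_population="east_asian"),
    marker("rs_ea_new", 1.5, 2e-8, east_asian_status="east_asian_discovered",
           discovery_population="east_asian"),
]
transferred = transform_panel(panel, ea_entries)
print("\nancestry transfer:")
for m in transferred.markers:
    print(f"  {m.rsid:14s} OR={m.or_per_allele:.2f} ({m.east_asian_status})")
print("  rs_strong swapped to the East-Asian OR, rs_replicated removed,")
print("  rs_candidate carried over untested, rs_ea_new appended.")

# --- Stage 3: LD pruning ------------------------------------------------------
# rs_strong and rs_candidate put in one high-LD block; the stronger P wins.
m = len(transferred.markers)
r2 = np.eye(m)
r2[0, 2] = r2[2, 0] = 0.92
pruned = ld_prune(transferred, r2, threshold=0.8)
print(f"\nLD pruning at r^2 < 0.8: {m} markers -> {len(pruned.markers)}:",
      [x.rsid for x in pruned.markers])
print("  the correlated pair kept its lower-P member (rs_strong).")
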