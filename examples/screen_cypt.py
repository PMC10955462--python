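"""Loss-of-function and structural screens on CYP^T.

Annotates the catalogued disruption alleles (exon-2 stop gain, 8-bp exon-1
frameshift, 2150-bp structural deletion), recovers the deletion from a
carrier's zero-depth run, and tallies discordant read-pair orientations.
"""

from slocus.cypt import (
    Variant,
    annotate_cds_consequence,
    classify_cypt_allele,
    detect_zero_depth_runs,
    flag_discordant_pairs,
)
from slocus.synth import CohortSpec, allele_specs, make_cohort_inputs

bundle = make_cohort_inputs(CohortSpec(preset="en6m"))
locus = bundle["locus"]
specs = allele_specs(locus)

print("Exonic consequences of the catalogued point/indel events:")
for label in ("CYP^T-2", "CYP^T-6"):
    ev = specs[label].events[0]
    call = annotate_cds_consequence(
        locus.cypt, locus.cds["CYP^T"], Variant("S_locus", ev.pos, ev.ref, ev.alt)
    )
    print(f"  {label}: {call.csq_class} in exon {call.exon} {call.protein_change}")

depth = bundle["depth"]
sub = depth[depth.chrom == "S_locus"]
ind = bundle["cohort"].individual.iloc[0]
deletions = detect_zero_depth_runs(
    sub[ind].to_numpy(), locus.cypt_screen_region, min_length=50,
    chrom="S_locus", positions=sub["pos"].to_numpy(), model=locus.cypt,
)
d = deletions[0]
print(f"\nZero-depth deletion in {ind}: {d.length} bp "
      f"({d.start}-{d.end}) overlapping {', '.join(d.overlapped_features[:4])}, ...")

counts = flag_discordant_pairs(bundle["pairs"], locus.cypt_screen_region, "S_locus")
print(f"\nRead-pair orientation tallies around CYP^T: {counts}")

allele = classify_cypt_allele([], deletions, locus.cypt, individual=ind)
print(f"\nAllele call for {ind}: {allele.allele} ({allele.functional_status})")
# The whole-exon-1 deletion is the CYP^T-8 signature: the gene and its
# proximal promoter motifs are gone, so the carrier is a homostyle.
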