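"""ceRNA sponge inference: set logic over predicted and validated layers.

Starting from miRNAs predicted to bind a lncRNA, intersect the union of
their validated mRNA targets with (a) significantly deregulated mRNAs and
(b) predicted direct lncRNA-mRNA partners. Genes in all three sets are the
triple-evidence candidates.
"""

from lnckit.network_sponge import infer_sponging

predicted_mirnas = {"miR-149", "miR-615"}
validated_targets = {
    "miR-149": {"LTBP-like-1", "GENE-A"},
    "miR-615": {"LTBP-like-1", "GENE-B"},
}
deregulated_mrnas = {"LTBP-like-1", "GENE-B", "GENE-C"}
predicted_direct_partners = {"LTBP-like-1", "GENE-D"}

res = infer_sponging(predicted_mirnas, validated_targets, deregulated_mrnas,
                     predicted_direct_partners)
print("validated targets of predicted miRNAs:", sorted(res.validated_targets))
print("sponge candidates (also deregulated): ", sorted(res.sponge_candidates))
print("direct candidates (also predicted):   ", sorted(res.direct_candidates))
print("triple candidates (all three layers): ", sorted(res.triple_candidates))
# A triple candidate is supported by a direct duplex prediction, validated
# miRNA targeting, and expression deregulation - the strongest working
# hypothesis for indirect regulation via miRNA sponging.
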