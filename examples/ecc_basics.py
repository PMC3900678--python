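"""Filter a raw interaction list and compute edge clustering coefficients.

ECC asks, for each interaction: of all the triangles this edge could close
given its endpoints' degrees, how many actually exist?  Interactions inside
dense complexes score near 1; peripheral ones score 0.
"""

from netloc import InteractionRecord, filter_interactions

records = [
    InteractionRecord("CDK4", "CCND1"),
    InteractionRecord("CCND1", "CDK4"),                         # duplicate
    InteractionRecord("CDK4", "CDK4"),                          # self-interaction
    InteractionRecord("CDK4", "CDKN2A"),
    InteractionRecord("CCND1", "CDKN2A"),
    InteractionRecord("CDKN2A", "MDM2", interaction_type="non-physical"),
    InteractionRecord("CCND1", "RB1"),
]

net, report = filter_interactions(records)
print(f"kept {report.n_edges} of {report.n_input} records "
      f"({report.removed_self_loops} self, {report.collapsed_duplicates} dup, "
      f"{report.removed_non_physical} non-physical removed)")

for u, v in sorted(net.edges):
    print(f"  {u:7s} - {v:7s}  z = {net.triangle_count(u, v)}  "
          f"ECC = {net.ecc(u, v):.2f}")

# The CDK4-CCND1-CDKN2A triangle gives those edges ECC 1: they are as
# clustered as their degrees allow, so each partner's evidence about the
# other's compartment is weighted maximally.  The pendant CCND1-RB1 edge
# closes no triangle and gets ECC 0.
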