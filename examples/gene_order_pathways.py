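"""Inversion pathways between the three named BZ gene orders.

The rpoB..psbZ region of fern plastomes occurs in an ancestral
(Angiopteris-type) and a derived (Adiantum-type) arrangement, plus a
third order known only from Plagiogyria japonica.  This example asks the
combinatorial questions behind the rearrangement hypotheses: how many
segment inversions separate the types, and which orders could be the
missing intermediate.
"""

from fernbz.gene_order import (
    enumerate_intermediates,
    inversion_distance,
    load_catalog,
)

catalog = load_catalog()
for name, order in catalog.items():
    print(f"{name:<12} {order}")

A, P, Ad = catalog["Angiopteris"], catalog["Plagiogyria"], catalog["Adiantum"]
print("\nminimum inversion counts (exhaustive search):")
print("  Angiopteris -> Plagiogyria:", inversion_distance(A, P))
print("  Plagiogyria -> Adiantum:   ", inversion_distance(P, Ad))
print("  Angiopteris -> Adiantum:   ", inversion_distance(A, Ad))

print("\norders one inversion from both Angiopteris and Adiantum:")
for mid in sorted(map(str, enumerate_intermediates(A, Ad))):
    marker = "  <- the Plagiogyria type" if mid == str(P) else ""
    print(f"  {mid}{marker}")

print(
    "\nThe Plagiogyria order sits exactly one inversion from each endpoint:"
    "\nit is a valid intermediate of the two-inversion pathway, or equally a"
    "\nback-inversion derivative of the derived order."
)
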