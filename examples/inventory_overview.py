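"""Summarize the packaged metabolite inventory.

Prints the per-category counts and the literature-saturation curve: how
many unique metabolites are known after including each successive review.
A flattening curve means additional reviews stop contributing new
metabolites, i.e. the inventory has saturated.
"""

from nanosorb import category_counts, cumulative_discovery, load_packaged_inventory

inv = load_packaged_inventory()
print(f"{len(inv)} unique enteric microbial metabolites\n")

print("category counts (multi-category metabolites counted in each):")
for cat, n in sorted(category_counts(inv).items(), key=lambda kv: -kv[1]):
    print(f"  {cat:<20s} {n:>3d}")

series = cumulative_discovery(inv, review_order=range(1, 11))
print("\ncumulative unique metabolites by number of reviews included:")
print("  " + " ".join(f"{c:4d}" for c in series))
frac = series[2] / series[-1]
print(f"\nThe first three reviews already report {frac:.1%} of the inventory;")
print("the flat tail of the curve is the saturation that justifies stopping.")
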