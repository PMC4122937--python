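"""Two-gene synteny and fragmentation conservation between assemblies.

Both statistics consume tables rather than raw sequence: a gene
homology table (with e-values and reciprocal-best flags) for synteny,
and two telomere-addition site sets plus a contig pairing for
fragmentation conservation.
"""

import pandas as pd

from nanoterm import HomologyTable, compare_site_sets, two_gene_synteny
from nanoterm.fragmentation import FragmentationSite

# --- two-gene synteny -----------------------------------------------------
rows = []
gm_a, gm_b = {}, {}
for i in range(10):
    gm_a[f"a{i}"] = [f"ga{i}.1", f"ga{i}.2"]
    gm_b[f"b{i}"] = [f"gb{i}.1", f"gb{i}.2"]
    rows.append((f"a{i}", f"ga{i}.1", f"b{i}", f"gb{i}.1", 1e-40, True))
    # the second gene matches the same partner contig only for i < 6
    target = f"b{i}" if i < 6 else f"b{(i + 1) % 10}"
    rows.append((f"a{i}", f"ga{i}.2", target, f"g{target}.2", 1e-25, False))
table = HomologyTable(pd.DataFrame(rows, columns=[
    "contig_a", "gene_a", "contig_b", "gene_b", "evalue", "reciprocal_best"]))

summary = two_gene_synteny(table, gm_a, gm_b)
print(f"two-gene contigs: {summary.n_two_gene_contigs}, syntenic: "
      f"{summary.n_syntenic} ({100 * summary.fraction_syntenic:.0f}%)")
# A two-gene contig is syntenic when both genes hit distinct genes on a
# single partner contig at e-value < 1e-10.

# --- fragmentation conservation -------------------------------------------
def site(cid, pos):
    return FragmentationSite(contig_id=cid, position=pos, end_sense="left",
                             support=5, is_terminal=False)

sites_a = [site(f"a{i}", 800) for i in range(4)]            # a0..a3 fragmented
sites_b = [site(f"b{i}", 805) for i in range(3)]            # b0..b2 fragmented
pairing = [(f"a{i}", f"b{i}") for i in range(10)]
cons = compare_site_sets(sites_a, sites_b, pairing, tolerance=10)
print(f"pairs with fragmentation in both/either: {cons.n_both}/{cons.n_either}"
      f" -> conservation {cons.fraction_conserved:.2f}")
print(f"per-site matches within 10 bp: {cons.site_matches}/{cons.site_total_a}")
# Conservation is the both/either fraction over contig pairs where at
# least one member shows alternative fragmentation.
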