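"""Summarize the packaged 57-gene azalea WRKY inventory.

Loads the transcribed family table, applies the curated phylogenetic
reassignment of the four zinc-finger-lost members, and prints the
group/subgroup counts and the per-gene duplication-type tally — the
family's published headline statistics.
"""
from wrkykit.classify import ClassificationResult, summarize_groups
from wrkykit.fixtures import load_fixtures

table1, candidates, reassignment, table2 = load_fixtures()

labels = table1.groups(reassignment)
results = [ClassificationResult(n, l, "fixture") for n, l in labels.items()]
s = summarize_groups(results)

print(f"family size: {s['total']} genes")
print(f"main groups: I={s['main_I']}  II={s['main_II']}  III={s['main_III']}")
print(
    "subgroups:  "
    + "  ".join(f"{sg}={s[sg]}" for sg in ("IIa", "IIb", "IIc", "IId", "IIe"))
)
print(f"zinc-finger-lost members: {[r.name for r in table1.zf_lost()]}")
print("duplication types:", table1.gene_type_tally())
print("\nfive-species subgroup reference:")
print(table2)
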