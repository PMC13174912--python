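"""Enumerate the symmetric-functionalization candidate library.

Filters the bundled 26-string substituent list for attachment valency,
then builds one candidate per (family, site, substituent) across the four
macrocycle families, appending the unfunctionalized parents and the
p-tert-butyl variants.
"""

from collections import Counter

from calixtda import bundled_substituents, enumerate_library, filter_substituents

records = filter_substituents(bundled_substituents())
by_status = Counter(r.status for r in records)
print(f"substituents: {len(records)} total, {dict(by_status)}")
for r in records:
    if r.status == "corrected":
        print(f"  corrected: {r.smiles!r} -> {r.corrected_smiles!r} ({r.reason})")

library = enumerate_library(substituents=records, include_manual_extras=True)
per_family = Counter(c.family for c in library)
print(f"\nlibrary: {len(library)} candidates")
for fam, n in sorted(per_family.items()):
    print(f"  {fam}: {n}")  # calix/aza have 4 sites (106), oxa/thia 3 (80)
print("example product:", library[0].candidate_id, library[0].product_smiles[:60], "...")
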