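"""Reconstruct integer 2x2 tables from printed odds-ratio / CI pairs.

Published association results often give only the OR and its 95% CI.
Because the cells are small integers bounded by the treated-patient count,
an exhaustive search can recover every table consistent with the printed
numbers - an audit that needs no patient-level data.
"""

from adrnet.association import odds_ratio, recover_table

cases = [
    ("cisplatin / cluster 0", (0.49, 56.80), 14, True),
    ("carboplatin / cluster 1", (0.46, 45.61), 30, False),
    ("pemetrexed / cluster 1", (0.63, 110.03), 70, False),
]

for label, ci, n_max, exact in cases:
    tables = recover_table(None, ci, n_max=n_max, exact_total=exact)
    bound = f"total {'=' if exact else '<='} {n_max}"
    print(f"{label}: CI {ci[0]}-{ci[1]}, {bound} -> {len(tables)} table(s)")
    for t in tables:
        o, lo, hi = odds_ratio(t).rounded()
        print(f"    ({t.a},{t.b},{t.c},{t.d})  OR {o}  CI [{lo}, {hi}]")
# Tables related by the (a<->d) diagonal swap share the same OR and CI, so
# matches come in symmetric pairs; all of them imply the same printed OR.
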