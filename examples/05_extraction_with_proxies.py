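"""Build an analysis dataset from a long association table with proxies.

Mimics the workflow of extracting exposure and outcome associations for a
chosen pair of (trait, study PubMed ID, ancestry) from a database export.
When a variant lacks an outcome association, a proxy variant in high LD
(r^2 at or above the threshold, default 0.6) stands in for it.
"""

import pandas as pd

from mrsummary import extract_pheno_csv, mr_ivw

cols = ["rsid", "trait", "pmid", "ancestry", "beta", "se",
        "effect_allele", "other_allele", "eaf", "proxy_rsid", "proxy_r2"]
records = pd.DataFrame([
    # exposure side: four variants, direct records
    ["rs11", "LDL cholesterol", 1001, "European", 0.31, 0.02, "A", "G", 0.3, None, None],
    ["rs22", "LDL cholesterol", 1001, "European", 0.24, 0.02, "C", "A", 0.4, None, None],
    ["rs33", "LDL cholesterol", 1001, "European", 0.19, 0.02, "T", "C", 0.2, None, None],
    ["rs44", "LDL cholesterol", 1001, "European", 0.16, 0.02, "G", "A", 0.6, None, None],
    # outcome side: rs22 only via a good proxy, rs33 only via a weak one
    ["rs11", "Coronary heart disease", 2002, "European", 0.065, 0.012, "A", "G", 0.3, None, None],
    ["rs22", "Coronary heart disease", 2002, "European", 0.050, 0.011, "C", "A", 0.4, "rs22b", 0.85],
    ["rs33", "Coronary heart disease", 2002, "European", 0.900, 0.013, "T", "C", 0.2, "rs33b", 0.45],
    ["rs44", "Coronary heart disease", 2002, "European", -0.031, 0.010, "A", "G", 0.4, None, None],
], columns=cols)

result = extract_pheno_csv(
    records,
    exposure="LDL cholesterol", pmid_e=1001, ancestry_e="European",
    outcome="Coronary heart disease", pmid_o=2002, ancestry_o="European",
    rsq_proxy=0.6,
)
print(result.data.to_frame().to_string(index=False))
print("Dropped:", result.dropped)
print()
print(mr_ivw(result.data))
print()
print("rs22 was filled in by its r^2=0.85 proxy; rs33's only proxy (0.45)")
print("fell below the threshold so the variant was dropped; rs44's outcome")
print("beta was sign-flipped during allele alignment.")
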