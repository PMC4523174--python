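"""Tissue-specific scores for catalogued prostate-enriched genes.

The score of a gene is its mean prostate FPKM divided by the maximum
mean FPKM in any other tissue: >= 50 means highly enriched, 5-50
moderately enriched.  Published catalogues print exactly these two
columns per gene, so the score can be recomputed from them; KLK3 is PSA,
the classic prostate marker.
"""

import pandas as pd

from tissuespec import tissue_specific_score
from tissuespec.simulate import TISSUES_27

CATALOG = [
    # gene, mean prostate FPKM, max FPKM in any other tissue
    ("KLK3", 4700.79, 5.76),
    ("ACPP", 1941.95, 37.20),
    ("SLC45A3", 369.97, 20.96),
    ("MSMB", 3181.86, 370.44),
]

print(f"{'gene':10s} {'prostate':>10s} {'max other':>10s} {'score':>8s}  tier")
for gene, target, max_other in CATALOG:
    row = pd.Series(0.0, index=list(TISSUES_27))
    row["prostate"], row["lung"] = target, max_other
    s = tissue_specific_score(row, "prostate")
    tier = "highly" if s >= 50 else "moderately" if s >= 5 else "-"
    print(f"{gene:10s} {target:10.2f} {max_other:10.2f} {s:8.2f}  {tier}")
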