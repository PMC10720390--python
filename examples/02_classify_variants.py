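"""Classify rare variants as P/LP/D (pathogenic / likely pathogenic /
deleterious) and flag carriers.

Rules: rare (MAF < 1%) truncating variants qualify outright; missense-like
variants need a ClinVar pathogenic/likely-pathogenic assertion by >= 1
laboratory or a unanimous in-silico predictor consensus; intronic/UTR/
synonymous/in-frame/near-splice classes are always excluded.
"""

from polyrisk import classify_variants, determine_carriers, generate_annotations
from polyrisk.synthetic_data import generate_rare_genotypes
import pandas as pd
import numpy as np

records, truth = generate_annotations(n_plpd=12, n_benign=20, seed=1)
results = classify_variants(records)

called = {r.variant_id for r in results if r.plpd}
expected = set(truth.loc[truth["plpd_truth"], "variant_id"])
print(f"classified {len(called)} of {len(records)} variants as P/LP/D "
      f"({len(called & expected)} true positives, {len(called - expected)} false positives)")
for r in results[:5]:
    print(f"  {r.variant_id}: plpd={r.plpd} rule={r.rule_fired}")

rng = np.random.default_rng(2)
ids = pd.Index([f"i{k}" for k in range(100)], name="individual_id")
carrier_truth = pd.Series(rng.random(100) < 0.08, index=ids)
geno = generate_rare_genotypes(carrier_truth, truth, seed=2)
carriers = determine_carriers(geno, results)
print(f"carriers: {int(carriers.sum())} of {len(carriers)} individuals "
      "(>= 1 alternate allele at >= 1 P/LP/D variant)")
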