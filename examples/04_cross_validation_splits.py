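"""Leakage-controlled cross-validation folds with certificates.

Three protocols: random (RSCV), structure-disjoint (SSCV: samples whose
complexes share a structural domain never cross folds) and
partner-disjoint (C3: no protein partner appears in two folds).
"""

from igmi import c3_folds, rscv_folds, sscv_folds
from igmi.splits import train_val_test_split

sample_to_complex = {f"mut{i}": f"complex{i % 8}" for i in range(40)}
complex_to_domains = {f"complex{c}": {f"ECOD.{c // 2}"} for c in range(8)}

fa = rscv_folds(list(sample_to_complex), k=5, seed=0)
print("RSCV fold sizes:", fa.fold_sizes)

fa = sscv_folds(sample_to_complex, complex_to_domains, k=4)
print("SSCV fold sizes:", fa.fold_sizes,
      "| domain overlaps:", len(fa.certificate["violations"]))

partners = {f"mut{i}": {f"P{i % 6}", f"Q{i % 3}"} for i in range(40)}
fa = c3_folds(partners, k=3)
print("C3 fold sizes:", fa.fold_sizes,
      "| partner overlaps:", len(fa.certificate["violations"]))

tr, val, te = train_val_test_split(fa, test_fold=0, seed=1)
print(f"8:1:1-style split from fold 0: {len(tr)} train / {len(val)} val / "
      f"{len(te)} test")
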