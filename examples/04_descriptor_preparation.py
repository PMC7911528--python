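"""Descriptor preparation on real structures: compute the 2D block from
SMILES, assign ion classes from pKa values, and run the curation steps
(normalization, intercorrelation filter, PCA space, outlier rules, split).
"""

import pandas as pd

from hsvr import descriptors, preprocess
from hsvr.simulate import worked_fixture

# structure-derived descriptors
for smiles in ("c1ccccc1", "CCO", "CC(=O)Oc1ccccc1C(=O)O"):
    vec = descriptors.compute_2d_descriptors(smiles)
    print(smiles, {k: round(v, 2) for k, v in vec.items() if k in
                   ("log_p", "psa", "n_ar", "hbd", "hba", "n_rot")})

# ion class from tagged pKa values (acid: all < 7; base: all > 7; ...)
print("naproxen-like:", descriptors.assign_ion_class([(4.2, "acidic")]))
print("amphoteric:", descriptors.assign_ion_class([(8.2, "acidic"), (6.1, "basic")]))

# curation on the pinned 12-compound fixture
cset, desc = worked_fixture()
matrix = cset.descriptors
normed, norm = preprocess.normalize(matrix)
retained, dropped = preprocess.filter_intercorrelated(normed, cset.response())
print(f"retained {len(retained)}/{len(matrix.columns)} descriptors after the "
      f"Spearman rho^2 >= 0.64 filter; dropped: {[d[0] for d in dropped]}")

space = preprocess.pca_space(normed[retained], n_components=3)
print("PC variance fractions:", [round(f, 3) for f in space["explained_variance_ratio"]])
outliers = preprocess.detect_outliers(space["scores"], descriptor_frame=desc)
print("outliers (structural rule: >9 rings or >12 HBAs):", sorted(outliers))
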