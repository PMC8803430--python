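"""Cell-fraction deconvolution and the mRNA stemness index.

Mixes known cell-type proportions into noisy bulk profiles and recovers
them by NNLS, then scores a cohort with a planted stemness gradient and
contrasts the index between response groups.
"""

import numpy as np
import pandas as pd

from tacesig.microenv import compare_fractions, deconvolve, stemness_index
from tacesig.simulate import generate_cohort, generate_mixtures

rng = np.random.default_rng(3)
sig = pd.DataFrame(
    rng.uniform(0.5, 10.0, size=(60, 3)),
    index=[f"g{i}" for i in range(60)],
    columns=["Tcell", "Macrophage", "Mast"],
)
raw = rng.uniform(size=(10, 3))
props = pd.DataFrame(
    raw / raw.sum(axis=1, keepdims=True),
    index=[f"s{i}" for i in range(10)],
    columns=sig.columns,
)
bulk = generate_mixtures(sig, props, noise_sd=0.3, seed=4)
recovered = deconvolve(bulk, sig)
err = np.abs(recovered.to_numpy() - props.to_numpy()).max()
print(f"max |recovered - true| over {len(props)} mixtures: {err:.4f}")

m, labels, truth = generate_cohort(
    40, 40, 300, 10, 1.0, seed=55, n_stemness_genes=60, stemness_shift=1.0
)
stem = stemness_index(m, truth.stemness_weights)
y = labels.to_numpy()
hi = stem["mRNAsi"].to_numpy()[y == 1].mean()
lo = stem["mRNAsi"].to_numpy()[y == 0].mean()
print(f"mean mRNAsi nonresponders {hi:.3f} vs responders {lo:.3f}")
# small recovery error despite noise, and a clearly higher stemness index
# in the nonresponse group, mirroring the planted gradient.
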