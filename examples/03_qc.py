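"""Run the SNP QC cascade on a fixture with planted violations.

The cascade applies, in a fixed logged order: locus reproducibility,
minor-allele count (> 3), mean read depth (5-25), one SNP per sequenced
fragment, monomorphic removal, individual missingness (> 20%), the exact
Hardy-Weinberg mid-p screen (< 0.01) and the |Fis| >= 0.5 screen, then
duplicate-genotype removal. Each planted violation is caught by exactly
the intended filter and re-running the cascade changes nothing.
"""

import numpy as np
import pandas as pd

from cohortnb import qc
from cohortnb.types import GenotypeMatrix

rng = np.random.default_rng(1)
n = 40
cols, names, meta = [], [], []


def add(dos, name, rep=1.0, depth=15.0, clone=None):
    cols.append(np.asarray(dos, float))
    names.append(name)
    meta.append({"reproducibility": rep, "depth": depth,
                 "clone_id": clone or f"clone_{name}"})


for i in range(20):
    p = rng.uniform(0.35, 0.65)
    add(rng.binomial(2, p, n).astype(float), f"good{i}")
add(rng.binomial(2, 0.4, n).astype(float), "low_reproducibility", rep=0.95)
mac3 = np.zeros(n); mac3[:3] = 1
add(mac3, "mac_three")          # minor-allele count exactly 3: removed
add(rng.binomial(2, 0.4, n).astype(float), "shallow", depth=3.0)
add(np.ones(n), "all_het")      # extreme heterozygote excess: HWE screen

calls = np.empty((n, len(names), 2), np.int16)
dos = np.column_stack(cols)
calls[:, :, 0] = (dos == 2)
calls[:, :, 1] = (dos >= 1)
m = GenotypeMatrix([f"s{i}" for i in range(n)], names, calls, pd.DataFrame(meta))

filtered, report = qc.run_qc(m)
print(f"{m.n_loci} loci in -> {filtered.n_loci} loci out\n")
for line in report.log:
    print(" ", line)
print("\nremoved per filter:")
for name, ids in report.removed_loci.items():
    if ids:
        print(f"  {name:20s} {ids}")
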