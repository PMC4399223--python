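"""Filter screen hits by target-gene expression.

A hit whose target gene is not expressed in any relevant cell population
is a likely off-target artifact.  This example TMM-normalizes a small
synthetic gene-count table over three sorted populations plus spheres,
calls genes expressed at average CPM > 0.5, and partitions a set of hit
genes by where they are expressed.
"""

import numpy as np
import pandas as pd

import hairpinscreen as hs

rng = np.random.default_rng(0)
genes = [f"gene{i}" for i in range(200)]
pops = ["Basal", "LP", "ML", "Sphere"]
counts = pd.DataFrame(rng.negative_binomial(5, 0.01, (200, 4)),
                      index=genes, columns=pops)
counts.iloc[:20] = 0                      # silent everywhere
counts.iloc[20:30, :3] = 0                # sphere-only genes
counts.iloc[30:40, 3] = 0                 # primary-only genes

factors = hs.tmm_factors(counts)
print("TMM factors:", ", ".join(f"{p}={f:.3f}" for p, f in factors.items()))

expr = hs.cpm(counts, norm_factors=factors)
calls = hs.expressed_calls(expr, threshold=0.5)

hit_genes = genes[:60]
xref = hs.cross_reference(hit_genes, calls, ["Basal", "LP", "ML"], "Sphere")
print(f"hit genes                    : {xref['n_hit_genes']}")
print(f"expressed in primary pops    : {xref['n_primary']} ({xref['pct_primary']}%)")
print(f"  of those, also in spheres  : {xref['n_primary_and_sphere']}")
print(f"sphere-only                  : {xref['n_sphere_only']}")
print(f"expressed nowhere (suspect)  : {xref['n_nowhere']} ({xref['pct_nowhere']}%)")

# microarray comparison: collapse multi-probe genes to their most
# expressed probe before matching platforms by symbol
probes = pd.DataFrame({"a": [5.0, 7.0, 2.0], "b": [4.0, 8.0, 1.0]},
                      index=["probe1", "probe2", "probe3"])
collapsed = hs.collapse_probes(probes, {"probe1": "geneX", "probe2": "geneX",
                                        "probe3": "geneY"})
print("\nprobe collapse keeps the brightest probe per gene:")
print(collapsed)
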