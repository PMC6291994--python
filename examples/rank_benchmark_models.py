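"""Rank the bundled benchmark homology models by SRI distance.

For each of the six benchmark proteins, ranks the five candidate model
SRI vectors against both the image-predicted SRI (DP_MOD) and the SRI
calculated from the deposited structure (DC_MOD). The two selections
agree for every protein, which is the point of the semi-empirical
approach: the experimentally derived SRI alone identifies the same best
model as the deposited structure would.
"""

from sriselect import benchmark_proteins, benchmark_vectors, rank_models

print(f"{'protein':14s} {'best by DP_MOD':>15s} {'best by DC_MOD':>15s}")
for protein in benchmark_proteins():
    bv = benchmark_vectors(protein)
    by_dp = rank_models(bv["models"], bv["predicted"])
    by_dc = rank_models(bv["models"], bv["calculated"])
    print(
        f"{protein:14s} {by_dp.best:>8s} ({by_dp.distances[by_dp.best]:5.2f} Å)"
        f" {by_dc.best:>8s} ({by_dc.distances[by_dc.best]:5.2f} Å)"
    )
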