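"""One replicate of the three-condition lineage-tracing benchmark.

Simulates a renewing tissue (256 cells, 1000 Moran steps), samples 100
cells, reconstructs neighbor-joining trees from (a) the exact VAF matrix,
(b) the matrix with VAF <= 0.01 zeroed and (c) simulated 50x sequencing
with 2-read support, and scores each against the recorded genealogy.
"""
from mtlineage.benchmark import PRESETS, run_replicate

result = run_replicate(PRESETS["desk"], seed=42)

n_cells = result.matrices["all_vaf"].n_cells
print(f"sampled {n_cells} cells; condition -> variants kept, CAS, closest-pair:")
for tag, report in result.reports.items():
    print(
        f"  {tag:14s} {result.matrices[tag].n_variants:4d} variants   "
        f"mean CAS {report.cas_mean:.3f}   "
        f"mean closest-pair distance {report.closest_pair_mean:.2f} divisions"
    )
print("\nCAS in [0,1]: how tightly each of the 20 ground-truth clones clusters")
print("in the reconstruction (1 = perfect). The closest-pair distance is the")
print("true genealogical distance (in cell divisions) between each cell and")
print("its reconstructed nearest neighbour — smaller is better. Discarding")
print("low-VAF variants or pushing the sample through 50x sequencing removes")
print("exactly the young variants that pin down recent relatives.")
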