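"""Call differentially/similarly accessible and hypomethylated regions.

Runs window QC on synthetic GpC accessibility counts, calls DAR/SAR
windows by accessibility dominance and DhMR/ShMR windows on CpG
methylation, then asks whether hypomethylated regions cluster around
accessible ones.
"""
from chromlink import (
    SimulationSpec,
    call_accessibility_regions,
    call_methylation_regions,
    cluster_fraction,
    generate_dataset,
    qc_filter,
)

ds = generate_dataset(SimulationSpec(seed=1))

passed, report = qc_filter(ds["acc_windows"])
print(f"QC ({report.variant}): {report.n_windows_in} windows in -> "
      f"{report.n_pass_coverage} coverage -> {report.n_pass_gc_balance} retained")

acc = call_accessibility_regions(passed)
print("accessibility calls:", acc["region_class"].value_counts().to_dict())

truth = ds["truth"].regions.query("kind == 'DAR'")
dars = acc[acc["region_class"] == "DAR"]
hit = set(zip(dars["chrom"], dars["start"])) & set(zip(truth["chrom"], truth["start"]))
print(f"planted DAR recall: {len(hit) / len(truth):.3f}")

meth = call_methylation_regions(ds["meth_windows"])
print("methylation calls:", meth["region_class"].value_counts().to_dict())

dhmrs = meth[meth["region_class"] == "DhMR"]
clu = cluster_fraction(dars, dhmrs, vicinity=10_000, n_perm=200, seed=1)
print(f"fraction of DARs with a DhMR within 10 kB: {clu['fraction']:.2f} "
      f"(permutation p = {clu['report'].p_value:.4g}, Jaccard {clu['jaccard']:.3f})")
print("Open chromatin and lineage-specific hypomethylation mark the same "
      "putative enhancers, so the two region sets co-cluster.")
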