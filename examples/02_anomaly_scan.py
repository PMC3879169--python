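"""Rediscover the deletion from array QC anomalies alone.

Carriers are hemizygous inside the deletion, so the in-deletion SNPs show
excess homozygosity (huge exact-test deviations) and inflated
parent-offspring conflicts. The scan flags runs of consecutive anomalous
markers as candidate deletion intervals.
"""

from lethalmap import arrayqc, simpop

cfg = simpop.PopulationConfig(
    breeds=[simpop.BreedConfig("RED", 150, 600, 1400, 0.128)],
    n_generations=1, n_markers_50k=600, n_markers_in_deletion_50k=5,
    n_markers_hd=0, n_markers_in_deletion_hd=0)
cohort = simpop.simulate_population(cfg, seed=7)
arr = simpop.emit_array_signals(cohort.phased, cohort.markers,
                                cohort.deletion, cfg.noise, seed=8)

filtered, report, samples = arrayqc.qc_filter(arr, pedigree=cohort.pedigree)
regions = arrayqc.anomaly_scan(report)

d = cohort.deletion
print(f"planted deletion: {d.start_bp:,}-{d.end_bp:,} ({d.length_bp:,} bp)")
for _, r in regions.iterrows():
    print(f"flagged region: {r['start']:,}-{r['end']:,} "
          f"({r['n_markers']} consecutive anomalous markers)")
worst = report.table.nsmallest(3, "hwe_p")
print("\nstrongest Hardy-Weinberg deviations (all excess homozygosity):")
for _, row in worst.iterrows():
    print(f"  {row['marker_id']}: p = {row['hwe_p']:.2e}, "
          f"{row['conflicts']} Mendelian conflicts")
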