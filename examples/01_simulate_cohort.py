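"""Generate a synthetic B-ALL study: 35 labeled patients, a 105-member
sex/age-matched reference pool, a gene catalog, and CMA-like aberration
segments with three planted region clusters."""

from cnaforest import SimulationConfig, qc_filter, simulate_study

config = SimulationConfig(seed=1)
study = simulate_study(config)

n_pos = sum(p.mrd_status == "positive" for p in study.patients)
print(f"patients: {len(study.patients)} ({n_pos} MRD+, "
      f"{len(study.patients) - n_pos} MRD-)")
print(f"reference pool: {len(study.references)}")
print(f"gene catalog: {len(study.catalog)} genes")
print(f"patient segments: {len(study.patient_segments)} "
      f"(all QC-valid: "
      f"{qc_filter(study.patient_segments) == study.patient_segments})")

for cluster in config.planted_clusters:
    r = cluster.region
    carriers = {
        s.sample_id for s in study.patient_segments
        if s.event_type == cluster.event_type
        and s.interval.chrom == r.chrom
        and s.interval.start <= r.end and r.start <= s.interval.end
    }
    pos = {p.sample_id for p in study.patients if p.mrd_status == "positive"}
    print(f"  planted {cluster.event_type:12s} {r.chrom}:{r.start}-{r.end}: "
          f"{len(carriers & pos)}/{n_pos} MRD+ carriers "
          f"(configured rate {cluster.freq_mrd_pos:.2f})")

# Carrier counts fluctuate binomially around the configured rates; the
# cnLOH cluster should be common among MRD+ patients, the mosaic losses
# less frequent.
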