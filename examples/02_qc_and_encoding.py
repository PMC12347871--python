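"""QC-filter segment calls and encode them into the binary gene x event
matrix the classifier consumes."""

from cnaforest import (
    SimulationConfig,
    encode,
    landscape_filter,
    qc_filter,
    simulate_study,
)

study = simulate_study(SimulationConfig(seed=1))
segments = qc_filter(study.patient_segments)
print(f"QC: {len(study.patient_segments)} -> {len(segments)} segments "
      "(the generator emits QC-valid calls by construction)")

landscape = landscape_filter(segments)
print(f"landscape view (>500 kb CNV, >5 Mb cnLOH): {len(landscape)} "
      "segments — reporting only, encoding uses all QC-passed calls")

sample_ids = [p.sample_id for p in study.patients]
matrix = encode(segments, study.catalog, sample_ids)
print(f"matrix: {len(matrix.sample_ids)} samples x "
      f"{len(matrix.features)} gene:event features")
print("first features:", matrix.feature_ids[:4])
print(f"mean carriers per feature: {matrix.values.sum(0).mean():.1f}")

# Each feature is 'SYMBOL:event' with mosaic losses merged into 'loss';
# an entry is 1 when any of the sample's segments of that event type
# overlaps the gene by at least one base.
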