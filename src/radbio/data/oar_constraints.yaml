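# Planning dose constraints for organs at risk and target coverage rules.
# Doses in GyE; percent limits refer to structure volume. "coverage_ge"
# doses are expressed as a fraction of the prescription dose.
- {structure: stomach, kind: max_dose, limit: 54.0}
- {structure: stomach, kind: volume_at_dose_le, dose: 50.0, limit: 2.0}
- {structure: stomach, kind: volume_at_dose_le, dose: 45.0, limit: 25.0}
- {structure: duodenum, kind: max_dose, limit: 55.0}
- {structure: duodenum, kind: volume_at_dose_le, dose: 45.0, limit: 33.0}
- {structure: small_bowel, kind: max_dose, limit: 54.0}
- {structure: small_bowel, kind: volume_at_dose_le, dose: 50.0, limit: 2.0}
- {structure: small_bowel, kind: volume_at_dose_le, dose: 45.0, limit: 25.0}
- {structure: kidneys, kind: volume_at_dose_le, dose: 18.0, limit: 50.0}
- {structure: kidneys, kind: volume_at_dose_le, dose: 23.0, limit: 30.0}
- {structure: liver, kind: mean_dose_le, limit: 30.0}
- {structure: spinal_cord, kind: max_dose, limit: 45.0}
- {structure: CTV, kind: coverage_ge, dose_fraction: 0.95, limit: 95.0}
- {structure: PTV, kind: coverage_ge, dose_fraction: 0.90, limit: 95.0}
- {structure: PTV, kind: hotspot_eq_zero, dose_fraction: 1.07}
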