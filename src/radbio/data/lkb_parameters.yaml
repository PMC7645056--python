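# Lyman-Kutcher-Burman NTCP parameter sets for upper-GI organs at risk,
# as published (point value plus reported range where available).
# td50 in Gy (EQD2 space), m and n dimensionless.
- organ: stomach
  endpoint: gastric bleed
  source: Pan et al.
  td50: 62.0
  td50_range: [53.0, 71.0]
  m: 0.30
  m_range: [0.23, 0.39]
  n: 0.07
  n_range: [0.03, 0.16]
- organ: stomach
  endpoint: ulceration/perforation
  source: Burman et al.
  td50: 65.0
  m: 0.14
  n: 0.15
- organ: duodenum
  endpoint: gastric bleed
  source: Pan et al.
  td50: 180.0
  td50_range: [100.0, 200.0]
  m: 0.39
  m_range: [0.36, 0.61]
  n: 0.12
  n_range: [0.09, 0.30]
- organ: duodenum
  endpoint: grade >=3 GI toxicity
  source: Holyoake et al.
  td50: 299.1
  m: 0.51
  n: 0.193
- organ: small_bowel
  endpoint: obstruction/perforation
  source: Burman et al.
  td50: 55.0
  m: 0.16
  n: 0.15
- organ: stoduo
  endpoint: gastric bleed
  source: Pan et al.
  td50: 52.5
  td50_range: [42.0, 64.0]
  m: 0.35
  m_range: [0.28, 0.47]
  n: 0.21
  n_range: [0.11, 0.50]
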