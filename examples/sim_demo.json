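{
 "n_msps": 30,
 "genes_per_msp": 100,
 "markers_per_msp": 100,
 "cohorts": [
  {"cohort_id": "coh_se_h",   "country": "SE", "region_class": "western",    "n_samples": 60},
  {"cohort_id": "coh_se_crc", "country": "SE", "region_class": "western",    "n_samples": 60, "disease_label": "CRC"},
  {"cohort_id": "coh_us_h",   "country": "US", "region_class": "western",    "n_samples": 60},
  {"cohort_id": "coh_us_crc", "country": "US", "region_class": "western",    "n_samples": 60, "disease_label": "CRC"},
  {"cohort_id": "coh_fj_h",   "country": "FJ", "region_class": "nonwestern", "n_samples": 60}
 ],
 "planted_disease_effects": [
  {"msp_id": "msp_0000", "disease_label": "CRC", "fold_change": 4.0},
  {"msp_id": "msp_0001", "disease_label": "CRC", "fold_change": 4.0},
  {"msp_id": "msp_0002", "disease_label": "CRC", "fold_change": 4.0},
  {"msp_id": "msp_0003", "disease_label": "CRC", "fold_change": 0.25},
  {"msp_id": "msp_0004", "disease_label": "CRC", "fold_change": 0.25}
 ],
 "planted_region_effects": [
  {"msp_id": "msp_0010", "fold_change": 5.0, "region_class": "nonwestern"}
 ],
 "planted_term_blocks": [
  {"block_id": "blkA", "n_terms": 6, "member_msp_ids": ["msp_0000", "msp_0001", "msp_0002", "msp_0005"], "category": "ko"},
  {"block_id": "blkB", "n_terms": 8, "member_msp_ids": ["msp_0010", "msp_0011", "msp_0012", "msp_0013"], "category": "cazyme"}
 ],
 "seed": 7
}
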