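{
 "description": "Published moment data for a prospective day-case surgery cohort: baseline (T0) and postoperative day-7 (T1) questionnaire sum scores plus two binary demographics (sex: 0=male/1=female; children: 0=no/1=yes). Binary means are prevalences with Bernoulli SDs. Correlations in correlations.csv (2 dp).",
 "n": 383,
 "n_enrolled": 398,
 "roster": [
  "sex",
  "children",
  "t0_stai_state",
  "t0_stai_trait",
  "t0_hads_a",
  "t0_mfi",
  "t0_stas_state",
  "t0_stas_trait",
  "t0_hads_d",
  "t0_gses",
  "t1_stai_state",
  "t1_stai_trait",
  "t1_hads_a",
  "t1_mfi",
  "t1_stas_state",
  "t1_stas_trait",
  "t1_hads_d"
 ],
 "means": {
  "sex": 0.437,
  "children": 0.518,
  "t0_stai_state": 38.1,
  "t0_stai_trait": 33.5,
  "t0_hads_a": 4.7,
  "t0_mfi": 41.6,
  "t0_stas_state": 10.2,
  "t0_stas_trait": 13.4,
  "t0_hads_d": 3.0,
  "t0_gses": 31.6,
  "t1_stai_state": 30.3,
  "t1_stai_trait": 30.5,
  "t1_hads_a": 2.9,
  "t1_mfi": 48.5,
  "t1_stas_state": 10.6,
  "t1_stas_trait": 13.1,
  "t1_hads_d": 2.8
 },
 "sds": {
  "sex": 0.496,
  "children": 0.4997,
  "t0_stai_state": 9.4,
  "t0_stai_trait": 8.1,
  "t0_hads_a": 3.1,
  "t0_mfi": 13.1,
  "t0_stas_state": 1.2,
  "t0_stas_trait": 3.6,
  "t0_hads_d": 2.4,
  "t0_gses": 4.2,
  "t1_stai_state": 8.9,
  "t1_stai_trait": 8.7,
  "t1_hads_a": 2.9,
  "t1_mfi": 17.0,
  "t1_stas_state": 2.5,
  "t1_stas_trait": 3.6,
  "t1_hads_d": 2.9
 }
}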