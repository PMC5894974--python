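,sex,children,t0_stai_state,t0_stai_trait,t0_hads_a,t0_mfi,t0_stas_state,t0_stas_trait,t0_hads_d,t0_gses,t1_stai_state,t1_stai_trait,t1_hads_a,t1_mfi,t1_stas_state,t1_stas_trait,t1_hads_d
sex,1.00,-0.03,0.27,0.16,0.18,0.12,-0.02,0.05,-0.02,-0.16,0.11,0.12,0.06,0.17,0.07,0.13,0.04
children,-0.03,1.00,-0.03,-0.07,-0.05,-0.07,-0.08,-0.05,0.05,0.09,0.04,-0.03,-0.02,0.03,0.07,0.00,0.09
t0_stai_state,0.27,-0.03,1.00,0.52,0.66,0.38,0.13,0.15,0.35,-0.24,0.42,0.45,0.35,0.29,0.15,0.25,0.26
t0_stai_trait,0.16,-0.07,0.52,1.00,0.66,0.54,0.15,0.47,0.55,-0.32,0.61,0.79,0.59,0.34,0.34,0.54,0.52
t0_hads_a,0.18,-0.05,0.66,0.66,1.00,0.42,0.11,0.27,0.48,-0.28,0.51,0.63,0.59,0.31,0.31,0.41,0.36
t0_mfi,0.12,-0.07,0.38,0.54,0.42,1.00,0.02,0.23,0.49,-0.27,0.51,0.52,0.40,0.54,0.21,0.25,0.43
t0_stas_state,-0.02,-0.08,0.13,0.15,0.11,0.02,1.00,0.25,0.00,0.08,0.13,0.16,0.14,0.04,0.16,0.09,0.09
t0_stas_trait,0.05,-0.05,0.15,0.47,0.27,0.23,0.25,1.00,0.20,-0.10,0.28,0.43,0.30,0.16,0.26,0.68,0.28
t0_hads_d,-0.02,0.05,0.35,0.55,0.48,0.49,0.00,0.20,1.00,-0.23,0.46,0.55,0.47,0.30,0.18,0.25,0.55
t0_gses,-0.16,0.09,-0.24,-0.32,-0.28,-0.27,0.08,-0.10,-0.23,1.00,-0.14,-0.27,-0.14,-0.11,-0.08,-0.15,-0.16
t1_stai_state,0.11,0.04,0.42,0.61,0.51,0.51,0.13,0.28,0.46,-0.14,1.00,0.76,0.71,0.58,0.51,0.45,0.66
t1_stai_trait,0.12,-0.03,0.45,0.79,0.63,0.52,0.16,0.43,0.55,-0.27,0.76,1.00,0.71,0.45,0.44,0.56,0.60
t1_hads_a,0.06,-0.02,0.35,0.59,0.59,0.40,0.14,0.30,0.47,-0.14,0.71,0.71,1.00,0.46,0.52,0.54,0.63
t1_mfi,0.17,0.03,0.29,0.34,0.31,0.54,0.04,0.16,0.30,-0.11,0.58,0.45,0.46,1.00,0.30,0.26,0.57
t1_stas_state,0.07,0.07,0.15,0.34,0.31,0.21,0.16,0.26,0.18,-0.08,0.51,0.44,0.52,0.30,1.00,0.54,0.45
t1_stas_trait,0.13,0.00,0.25,0.54,0.41,0.25,0.09,0.68,0.25,-0.15,0.45,0.56,0.54,0.26,0.54,1.00,0.40
t1_hads_d,0.04,0.09,0.26,0.52,0.36,0.43,0.09,0.28,0.55,-0.16,0.66,0.60,0.63,0.57,0.45,0.40,1.00
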