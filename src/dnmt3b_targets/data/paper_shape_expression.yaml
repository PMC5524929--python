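# Packaged expression scenario mirroring the study's shape: the 32-gene human
# panel measured in 14 case and 5 control neurosphere cultures, probe-array
# chemistry for 30 genes (ceiling Ct 32) and dye chemistry for the two
# ribosomal/lincRNA assays (ceiling Ct 35).
#
# expressed + ddct < 0  -> planted up-regulated in cases (9 genes)
# expressed + ddct = 0  -> expressed, no group difference (3 genes)
# expressed: false      -> ceiling-censored / undetermined draws (20 genes)
seed: 92942
n_case: 14
n_control: 5
missing_rate_nonexpressed: 0.3
controls:
  probe_array: {symbol: S18, ct_mean: 12.0, ct_sd: 0.3}
  dye: {symbol: GAPDH, ct_mean: 16.0, ct_sd: 0.3}
genes:
  - {symbol: KPNA1,     chemistry: probe_array, expressed: true,  baseline_ct: 26.0, sd: 0.5, ddct: -3.0}
  - {symbol: EED,       chemistry: probe_array, expressed: true,  baseline_ct: 25.5, sd: 0.5, ddct: -2.5}
  - {symbol: SULF1,     chemistry: probe_array, expressed: true,  baseline_ct: 27.0, sd: 0.5, ddct: -3.5}
  - {symbol: CDK5RAP2,  chemistry: probe_array, expressed: true,  baseline_ct: 26.5, sd: 0.5, ddct: -2.0}
  - {symbol: BBX,       chemistry: probe_array, expressed: true,  baseline_ct: 25.0, sd: 0.5, ddct: -3.0}
  - {symbol: DRG1,      chemistry: probe_array, expressed: true,  baseline_ct: 24.0, sd: 0.5, ddct: -2.5}
  - {symbol: RAB10,     chemistry: probe_array, expressed: true,  baseline_ct: 24.5, sd: 0.5, ddct: -3.0}
  - {symbol: MYDGF,     chemistry: probe_array, expressed: true,  baseline_ct: 26.0, sd: 0.5, ddct: -4.0}
  - {symbol: RNA45S5,   chemistry: dye,         expressed: true,  baseline_ct: 20.0, sd: 0.5, ddct: -3.0}
  - {symbol: STAT3,     chemistry: probe_array, expressed: true,  baseline_ct: 25.0, sd: 0.5, ddct: 0.0}
  - {symbol: DPP9,      chemistry: probe_array, expressed: true,  baseline_ct: 27.5, sd: 0.5, ddct: 0.0}
  - {symbol: NEDD4L,    chemistry: probe_array, expressed: true,  baseline_ct: 26.5, sd: 0.5, ddct: 0.0}
  - {symbol: MYO7A,     chemistry: probe_array, expressed: false, baseline_ct: 35.0, sd: 1.0, ddct: 0.0}
  - {symbol: ANO2,      chemistry: probe_array, expressed: false, baseline_ct: 35.0, sd: 1.0, ddct: 0.0}
  - {symbol: CHL1,      chemistry: probe_array, expressed: false, baseline_ct: 35.0, sd: 1.0, ddct: 0.0}
  - {symbol: LIMD1,     chemistry: probe_array, expressed: false, baseline_ct: 35.0, sd: 1.0, ddct: 0.0}
  - {symbol: CYR61,     chemistry: probe_array, expressed: false, baseline_ct: 35.0, sd: 1.0, ddct: 0.0}
  - {symbol: GPHN,      chemistry: probe_array, expressed: false, baseline_ct: 35.0, sd: 1.0, ddct: 0.0}
  - {symbol: SFI1,      chemistry: probe_array, expressed: false, baseline_ct: 35.0, sd: 1.0, ddct: 0.0}
  - {symbol: DOPEY2,    chemistry: probe_array, expressed: false, baseline_ct: 35.0, sd: 1.0, ddct: 0.0}
  - {symbol: SMO,       chemistry: probe_array, expressed: false, baseline_ct: 35.0, sd: 1.0, ddct: 0.0}
  - {symbol: C10ORF67,  chemistry: probe_array, expressed: false, baseline_ct: 35.0, sd: 1.0, ddct: 0.0}
  - {symbol: TMEM125,   chemistry: probe_array, expressed: false, baseline_ct: 35.0, sd: 1.0, ddct: 0.0}
  - {symbol: KIAA0825,  chemistry: probe_array, expressed: false, baseline_ct: 35.0, sd: 1.0, ddct: 0.0}
  - {symbol: LY75,      chemistry: probe_array, expressed: false, baseline_ct: 35.0, sd: 1.0, ddct: 0.0}
  - {symbol: EIF4ENIF1, chemistry: probe_array, expressed: false, baseline_ct: 35.0, sd: 1.0, ddct: 0.0}
  - {symbol: PPP2R2B,   chemistry: probe_array, expressed: false, baseline_ct: 35.0, sd: 1.0, ddct: 0.0}
  - {symbol: LITAF,     chemistry: probe_array, expressed: false, baseline_ct: 35.0, sd: 1.0, ddct: 0.0}
  - {symbol: NEUROG1,   chemistry: probe_array, expressed: false, baseline_ct: 35.0, sd: 1.0, ddct: 0.0}
  - {symbol: ADAM8,     chemistry: probe_array, expressed: false, baseline_ct: 35.0, sd: 1.0, ddct: 0.0}
  - {symbol: NEDD4,     chemistry: probe_array, expressed: false, baseline_ct: 35.0, sd: 1.0, ddct: 0.0}
  - {symbol: LINC01603, chemistry: dye,         expressed: false, baseline_ct: 38.0, sd: 1.0, ddct: 0.0}
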