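# Packaged variant scenario mirroring the WES cohort shape: 56 patients
# screened across the expressed panel genes, with per-database MAF draws
# straddling the 0.01 rare threshold.
seed: 92942
n_patients: 56
genes: [KPNA1, EED, SULF1, CDK5RAP2, BBX, DRG1, RAB10, MYDGF, RNA45S5,
        STAT3, DPP9, NEDD4L]
n_variants: 40
weight_rare: 0.3
weight_common: 0.5
weight_absent: 0.2
db_presence: 0.7
databases: [KG_ALL, KG_EUR, EVS, ExAC, MGP]
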