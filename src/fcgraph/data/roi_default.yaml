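# Default region-of-interest composition for the motor correlation analysis.
# Keys are ROI names; values are lists of region-table abbreviations whose
# nodes are pooled (per hemisphere). Fully overridable from the pipeline
# config; the premotor / supplementary-motor split is an interpretation and
# deliberately configurable.
SM1: [PrCG, PoCG]     # primary sensorimotor cortex
SMA: [MlFG]           # supplementary motor area (medial frontal nodes)
PMC: [SFG, MFG]       # premotor cortex (lateral superior/middle frontal nodes)
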