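# Transcription of published percent AUC reductions for the rifampicin DDI set
# (PBPK-simulated, mechanistic-static, and clinically observed columns).
# These are reference numbers for comparison tables and figures only; nothing
# in the computational pipeline reads them as inputs.
victim,pct_pbpk_published,pct_msm_published,pct_observed
midazolam,91.4,87.1,94.7
alfentanil,90.3,86.7,94.5
atorvastatin,79.9,79.6,80.2
omeprazole,86.4,64.2,86.1
pioglitazone,54.03,31.4,56.3
tolbutamide,59.8,25.8,63.5
glyburide,38.2,74.1,38.9
bupropion,67.6,53.4,67.2
repaglinide,56.5,31.4,57.5
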