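variable,klass,proportion_pct,area_km2
carbon_storage,ESI,7.23,2449.82
carbon_storage,SI,1.38,467.78
carbon_storage,NSC,89.85,30441.53
carbon_storage,SD,1.54,522.15
carbon_storage,ESD,0.00,0.00
nep,ESI,21.43,7259.79
nep,SI,5.84,1978.41
nep,NSC,57.19,19377.06
nep,SD,4.94,1672.85
nep,ESD,10.61,3593.18
carbon_balance,ESI,18.91,6406.04
carbon_balance,SI,4.56,1545.57
carbon_balance,NSC,55.04,18647.01
carbon_balance,SD,5.28,1787.97
carbon_balance,ESD,16.22,5494.70
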