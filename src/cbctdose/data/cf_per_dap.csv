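device,age_group,cf_usv_per_dapcm2
accuitomo170,4-6y,16.7
accuitomo170,7-11y,11.7
accuitomo170,12-14y,8.58
accuitomo170,>=15y,7.55
newtom_vgi_evo,4-6y,19.2
newtom_vgi_evo,7-11y,12.9
newtom_vgi_evo,12-14y,9.15
newtom_vgi_evo,>=15y,7.96
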