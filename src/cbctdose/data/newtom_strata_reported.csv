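device,age_group,fov_category,mode,n,mean_corrected_dap_dgycm2
newtom_vgi_evo,4-6y,small,HR,1,3.47
newtom_vgi_evo,4-6y,medium,standard,1,3.15
newtom_vgi_evo,4-6y,medium,HR,4,4.71
newtom_vgi_evo,4-6y,large,standard,3,6.09
newtom_vgi_evo,7-11y,small,standard,1,0.94
newtom_vgi_evo,7-11y,small,HR,12,3.78
newtom_vgi_evo,7-11y,medium,standard,52,2.12
newtom_vgi_evo,7-11y,medium,HR,144,6.19
newtom_vgi_evo,7-11y,large,standard,18,7.51
newtom_vgi_evo,12-14y,small,standard,3,1.04
newtom_vgi_evo,12-14y,small,HR,10,3.96
newtom_vgi_evo,12-14y,medium,standard,81,2.48
newtom_vgi_evo,12-14y,medium,HR,75,7.14
newtom_vgi_evo,12-14y,large,standard,55,7.64
newtom_vgi_evo,>=15y,small,standard,3,1.16
newtom_vgi_evo,>=15y,small,HR,55,4.72
newtom_vgi_evo,>=15y,medium,standard,2263,2.93
newtom_vgi_evo,>=15y,medium,HR,796,8.59
newtom_vgi_evo,>=15y,large,standard,1390,7.73
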