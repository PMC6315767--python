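sample_id,group,arachidonic_acid,eicosatrienoic_acid
HC01,HC,47.6,112.4
HC02,HC,13.6,10
HC03,HC,25.6,19.6
HC04,HC,7.6,3.6
HC05,HC,15.2,2
HC06,HC,63.6,210.4
HC07,HC,86.8,136.4
HC08,HC,144.8,127.6
HC09,HC,12.8,5.6
HC10,HC,13.2,16.4
HC11,HC,34.8,60
PA01,PA,4406,3854.4
PA02,PA,4365.2,1671.6
PA03,PA,432.4,492.4
PA04,PA,1644.8,9462.4
PA05,PA,92,514.4
PA06,PA,3510,3600.4
PA07,PA,98,196
PA08,PA,44.8,904.8
PA09,PA,27.6,181.6
PA10,PA,14.0,50.0
PA11,PA,4262.8,1029.2
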