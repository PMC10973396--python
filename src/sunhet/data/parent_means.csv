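genotype,line_type,DFI,DFC,PH,LA,HD,SC,LP,HSW,SYP
CMS-HAP-54,CMS,48.5,59,200.14,214.56,17.1,22.05,31.8,5.24,62.83
CMS-HAP-56,CMS,48.5,59,188.45,257.48,17.85,40,29.5,5.11,63.29
CMS-HAP-112,CMS,46.5,55.5,192.15,197.32,18.15,45.5,33.1,5.11,68.19
CMS-HAP-111,CMS,48.5,55,134.6,233.65,17.3,48,23.35,5.65,56.85
CMS-HAP-12,CMS,49,57.5,200,171.17,17,45.7,29,5.87,57.05
CMS-HAP-99,CMS,49.5,58,186.85,189.8,19.3,26.3,33,6.61,65.05
RHP-68,R,55,63.5,161.45,167.27,14.55,15.65,25.9,4.26,27.28
RHP-41,R,56.5,67.5,180.75,220.3,11.05,9.55,30,3.52,27.9
RHP-38,R,52,63.5,166.5,141.5,10.45,12.95,27.55,4.04,30.29
RHP-53,R,50.5,60.5,181.4,191.4,13,14.1,32.65,4.04,32.37
RHP-71,R,55,62,154.35,168.7,12.95,6.95,26.1,3.49,30.8
RHP-69,R,53.5,61.5,138.55,148.15,11.4,15.7,30.5,3.48,27.45
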