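cross,DFI,DFC,PH,LA,HD,SC,LP,HSW,SYP
RHP-68 × CMS-HAP-56,45,53,146.13,138.77,18.38,63.38,32.5,5.77,59.24
RHP-68 × CMS-HAP-111,47,55,148.08,152.8,19.48,66.63,31.83,5.6,75.25
RHP-68 × CMS-HAP-112,44,50,137.75,161.71,17.11,59.5,29.33,5.37,50.97
RHP-68 × CMS-HAP-12,49,57,152.79,141.2,20.99,65.42,28.67,6.1,88.93
RHP-68 × CMS-HAP-54,47,55.5,129.42,156.03,17.53,48.83,28.67,6.01,81.5
RHP-68 × CMS-HAP-99,47,53.5,159.33,134.89,19.25,77.5,30.17,5.8,72.32
RHP-41 × CMS-HAP-111,50,56,157.8,145.15,20.18,66.79,33,6.43,99.45
RHP-41 × CMS-HAP-12,50,56,137,145.6,20.16,61.67,27.67,6.38,87.93
RHP-41 × CMS-HAP-54,47.5,53.5,145.67,174.44,19.33,58.33,28.17,5.77,61
RHP-41 × CMS-HAP-56,46,52.5,132,133.17,19.79,56.83,29,6.07,68.12
RHP-41 × CMS-HAP-112,45,51.5,141,129.65,19.99,59.67,29.33,6.03,73.21
RHP-41 × CMS-HAP-99,49,57.5,157.5,166.2,21.18,63,34,6.59,92.98
RHP-38 × CMS-HAP-111,48.5,56.5,171.5,152.23,19.55,64.33,31.67,4.77,60.63
RHP-38 × CMS-HAP-56,45,51,153.5,142.55,18.14,74.83,29.83,6.26,70.92
RHP-38 × CMS-HAP-112,44,50.5,145.5,148.44,17.52,69.33,32.67,6.55,64.74
RHP-38 × CMS-HAP-54,44.5,50,139.33,178.5,19.65,64.83,33.17,7.07,72.66
RHP-38 × CMS-HAP-12,49.5,55.5,159.17,162.01,21.89,57.67,33.83,7.34,74.82
RHP-38 × CMS-HAP-99,47.5,55,155.5,155.7,21.25,55,33.33,6.63,79.6
RHP-53 × CMS-HAP-111,49.5,56,131,160.07,22.77,57.83,26,4.94,49.3
RHP-53 × CMS-HAP-54,45,51,130.88,161.92,18.95,51.17,27,6.17,59.53
RHP-53 × CMS-HAP-12,49,55.5,137,165,19.38,60.33,32.33,5.48,57.92
RHP-53 × CMS-HAP-112,45,51.5,135.17,162.62,18.95,57.33,29.83,5.63,49.38
RHP-53 × CMS-HAP-99,47.5,55,144.83,165.02,19.07,66.33,33.33,6.3,65.26
RHP-53 × CMS-HAP-56,45,51,149,146.57,19.57,62.5,29,7.01,61.88
RHP-71 × CMS-HAP-99,56,64,155,173.29,23.95,60.5,36.17,5.6,92.89
RHP-71 × CMS-HAP-56,56.5,65.5,161.33,176.53,21.89,55.33,36.67,5.71,92.24
RHP-71 × CMS-HAP-112,55,64,175.17,158.77,22.54,55,36.33,5.21,87.77
RHP-71 × CMS-HAP-111,57,66.5,162.33,169.77,22.61,58.83,35.5,4.41,90.93
RHP-71 × CMS-HAP-54,56,64,164.17,169.14,21.79,60.5,36,5.1,103.36
RHP-71 × CMS-HAP-12,57,64,151,163.07,22.39,55.17,35.67,5.57,98.91
RHP-69 × CMS-HAP-12,49,54.5,156.5,146.4,20.98,59.83,29.5,6.23,73.57
RHP-69 × CMS-HAP-112,45,51.5,141.33,132.38,17.81,57.5,30.67,5.9,60.71
RHP-69 × CMS-HAP-111,49.5,54.5,137,144.71,19.82,52.83,33.5,5.57,70.66
RHP-69 × CMS-HAP-56,46,51.5,141.33,143.27,18.5,57.5,29.83,6.77,66.72
RHP-69 × CMS-HAP-54,46.5,52,146.5,126.04,18.01,55,31.83,6.73,74.13
RHP-69 × CMS-HAP-99,49.5,54,149.54,149.43,18.01,70.04,29,6.76,71.67
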