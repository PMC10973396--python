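line,tester,DFI_mph,DFI_bph,DFC_mph,DFC_bph,PH_mph,PH_bph,LA_mph,LA_bph,HD_mph,HD_bph,SC_mph,SC_bph,LP_mph,LP_bph,HSW_mph,HSW_bph,SYP_mph,SYP_bph
CMS-HAP-56,RHP-68,-13.04,-18.18,-13.47,-16.54,-16.48,-22.46,-34.66,-46.11,13.43,2.94,127.76,58.44,17.33,10.17,23.22,12.92,30.82,-6.39
CMS-HAP-56,RHP-41,-12.38,-18.58,-17,-22.22,-28.49,-29.95,-44.26,-48.28,36.96,10.87,129.4,42.09,-2.52,-3.33,40.59,18.79,49.4,7.63
CMS-HAP-56,RHP-38,-10.45,-13.46,-16.73,-19.69,-13.51,-18.55,-28.54,-44.64,28.2,1.62,182.66,87.09,4.59,1.14,36.65,22.41,51.58,12.06
CMS-HAP-56,RHP-53,-9.09,-10.89,-14.64,-15.7,-19.43,-20.93,-34.7,-43.08,26.9,9.66,131.05,56.25,-6.68,-11.18,53.14,37.18,29.37,-2.23
CMS-HAP-56,RHP-71,9.18,2.73,8.26,5.65,-5.87,-14.39,-17.16,-31.44,42.14,22.63,135.72,38.34,31.89,24.29,32.75,11.64,96.08,45.75
CMS-HAP-56,RHP-69,-9.8,-14.02,-14.52,-16.26,-13.56,-25,-29.36,-44.36,26.5,3.64,106.46,43.75,-0.55,-2.18,57.72,32.49,47.07,5.43
CMS-HAP-111,RHP-68,-9.18,-14.55,-7.17,-13.39,0.04,-8.28,-23.78,-34.6,22.32,12.6,109.35,38.8,29.26,22.9,13.07,-0.88,78.89,32.37
CMS-HAP-111,RHP-41,-4.76,-11.5,-8.57,-17.04,0.08,-12.7,-36.05,-37.88,42.4,16.68,132.13,39.16,23.71,10,40.16,13.81,134.69,74.93
CMS-HAP-111,RHP-38,-3.48,-6.73,-4.64,-11.02,13.92,3,-18.84,-34.85,40.94,13.03,111.11,34.03,24.44,14.95,-1.5,-15.49,39.16,6.65
CMS-HAP-111,RHP-53,0,-1.98,-3.03,-7.44,-17.09,-27.78,-24.68,-31.5,50.33,31.65,86.25,20.48,-7.14,-20.37,2.01,-12.48,10.52,-13.27
CMS-HAP-111,RHP-71,10.14,3.65,13.68,7.26,12.36,5.17,-15.61,-27.34,49.52,30.72,114.12,22.56,43.58,36.02,-3.45,-21.95,107.48,59.95
CMS-HAP-111,RHP-69,-2.94,-7.48,-6.44,-11.38,0.31,-1.12,-24.19,-38.06,38.08,14.54,65.87,10.06,24.42,9.84,22.08,-1.42,67.64,24.29
CMS-HAP-112,RHP-68,-13.3,-20,-15.97,-21.26,-22.09,-28.31,-11.29,-18.04,4.65,-5.73,94.6,30.77,-0.56,-11.37,14.79,5.19,6.78,-25.25
CMS-HAP-112,RHP-41,-12.62,-20.35,-16.26,-23.7,-24.38,-26.62,-37.91,-41.15,36.92,10.14,116.77,31.13,-7.04,-11.39,39.55,17.91,52.4,7.38
CMS-HAP-112,RHP-38,-10.66,-15.38,-15.13,-20.47,-18.86,-24.28,-12.37,-24.77,22.55,-3.44,137.25,52.38,7.73,-1.3,43.09,28.18,31.48,-5.06
CMS-HAP-112,RHP-53,-7.22,-10.89,-11.21,-14.88,-27.63,-29.66,-16.33,-17.59,21.67,4.41,92.4,26.01,-9.25,-9.86,22.88,10.08,-1.79,-27.58
CMS-HAP-112,RHP-71,8.37,0,8.94,3.23,1.11,-8.84,-13.25,-19.54,44.95,24.19,109.72,20.88,22.74,9.76,21.12,1.86,77.34,28.72
CMS-HAP-112,RHP-69,-10,-15.89,-11.97,-16.26,-14.52,-26.45,-23.36,-32.91,20.58,-1.85,87.91,26.37,-3.55,-7.34,37.33,15.36,26.97,-10.96
CMS-HAP-12,RHP-68,-5.77,-10.91,-5.79,-10.24,-15.46,-23.6,-16.56,-17.51,33.09,23.5,113.25,43.14,4.43,-1.16,20.45,3.92,110.89,55.87
CMS-HAP-12,RHP-41,-5.21,-11.5,-10.4,-17.04,-28.04,-31.5,-25.61,-33.91,43.78,18.62,123.22,34.93,-6.2,-7.77,35.89,8.78,107.02,54.13
CMS-HAP-12,RHP-38,-1.98,-4.81,-8.26,-12.6,-13.14,-20.42,3.63,-5.35,59.49,28.76,96.64,26.18,19.65,16.66,48.03,25.06,71.35,31.16
CMS-HAP-12,RHP-53,-1.51,-2.97,-5.93,-8.26,-28.16,-31.5,-8.98,-13.79,29.17,13.97,101.79,32.02,4.88,-0.98,10.6,-6.56,29.56,1.53
CMS-HAP-12,RHP-71,9.62,3.64,7.11,3.23,-14.77,-24.5,-4.04,-4.74,49.52,31.71,109.55,20.71,29.46,22.98,19.25,-4.94,125.18,73.37
CMS-HAP-12,RHP-69,-4.39,-8.41,-8.4,-11.38,-7.55,-21.75,-8.31,-14.47,47.78,23.44,94.9,30.93,-0.84,-3.28,33.4,6.22,74.13,28.96
CMS-HAP-54,RHP-68,-9.18,-14.55,-9.39,-12.6,-28.42,-35.34,-18.27,-27.28,10.74,2.49,159.07,121.47,-0.64,-9.86,26.53,14.59,80.89,29.73
CMS-HAP-54,RHP-41,-9.52,-15.93,-15.42,-20.74,-23.51,-27.22,-19.77,-20.82,37.3,13.01,269.21,164.56,-8.85,-11.43,31.7,10.1,34.47,-2.9
CMS-HAP-54,RHP-38,-11.44,-14.42,-18.37,-21.26,-24,-30.38,0.26,-16.81,42.69,14.94,270.46,194.01,11.76,4.29,52.21,34.8,56.06,15.65
CMS-HAP-54,RHP-53,-9.09,-10.89,-14.64,-15.7,-31.4,-34.61,-20.23,-24.54,25.91,10.82,183.1,132.06,-16.21,-17.3,32.83,17.64,25.06,-5.25
CMS-HAP-54,RHP-71,8.21,1.82,5.79,3.23,-7.38,-17.97,-11.74,-21.17,45.02,27.43,317.24,174.38,24.35,13.21,16.84,-2.76,120.81,64.53
CMS-HAP-54,RHP-69,-8.82,-13.08,-13.69,-15.45,-13.49,-26.8,-30.5,-41.26,26.39,5.32,191.39,149.43,2.2,0.11,54.24,28.22,64.24,18
CMS-HAP-99,RHP-68,-10.05,-14.55,-11.93,-15.75,-8.51,-14.73,-24.44,-28.93,13.74,-0.26,269.49,194.68,2.44,-8.58,6.81,-12.19,56.66,11.18
CMS-HAP-99,RHP-41,-7.55,-13.27,-8.37,-14.81,-14.31,-15.71,-18.95,-24.56,39.54,9.72,251.46,139.54,7.94,3.03,30.11,-0.23,100.05,42.93
CMS-HAP-99,RHP-38,-6.4,-8.65,-9.47,-13.39,-11.99,-16.78,-6.01,-17.97,42.89,10.13,180.25,109.13,10.11,1.02,24.6,0.45,67,22.38
CMS-HAP-99,RHP-53,-5,-5.94,-7.17,-9.09,-21.34,-22.49,-13.42,-13.78,18.11,-1.17,228.39,152.22,1.55,1.02,18.4,-4.54,33.99,0.33
CMS-HAP-99,RHP-71,7.18,1.82,6.67,3.23,-9.14,-17.05,-3.32,-8.7,48.56,24.12,263.91,130.04,22.39,9.59,11,-15.22,93.82,42.8
CMS-HAP-99,RHP-69,-3.88,-7.48,-9.62,-12.2,-8.09,-19.97,-11.57,-21.27,17.33,-6.68,233.52,166.31,-8.66,-12.12,34.03,2.27,54.96,10.18
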