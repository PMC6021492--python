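cell_line,driver_mutation,HLA-ABC_pre,HLA-ABC_post,HLA-DR_pre,HLA-DR_post,NGFR_pre,NGFR_post,PD-L1_pre,PD-L1_post,PD-L2_pre,PD-L2_post
A2058,BRAF V600E,32.9,139.1,2.5,66.7,398.7,218.6,1.0,9.8,1.9,7.7
SKMel28,BRAF V600E,74.2,128.3,11.1,120.8,44.7,197.3,1.3,2.9,2.6,10.0
C060M1,BRAF V600E,34.9,88.7,29.5,75.7,10.4,16.3,1.0,5.5,4.3,6.7
SCC14-0257,BRAF V600K,15.8,64.8,12.8,102.2,347.3,722.7,0.9,2.5,1.4,5.9
MM418,BRAF V600E,38.2,81.8,1.2,7.7,16.0,19.0,1.1,4.0,1.1,1.5
NM16,BRAF V600E,21.7,62.5,7.0,76.5,1808.8,2833.0,0.8,3.4,7.8,17.1
NM182,BRAF V600E,18.9,143.6,1.3,31.8,10.1,14.0,1.0,4.5,1.0,1.6
MM200,BRAF V600E,35.1,202.0,7.2,141.0,450.7,1505.6,1.0,4.0,1.2,3.4
NM39,BRAF V600E,43.6,122.2,27.6,123.3,90.7,46.7,1.1,3.9,4.3,17.9
HT144,BRAF V600E,23.4,43.4,71.4,100.3,353.1,292.9,1.1,3.2,4.9,12.0
C016M,BRAF V600E,20.9,70.3,42.7,95.9,469.6,630.2,0.9,1.3,2.2,5.5
MelRm,NRAS Q61R,36.9,98.7,102.8,252.5,18.4,75.2,0.9,2.3,1.6,3.4
NM47,NRAS Q61R,42.1,109.0,157.9,249.0,213.6,1034.1,1.0,2.5,1.8,2.9
NM177,NRAS Q61R,56.5,99.7,76.6,92.9,3674.9,3663.2,1.0,1.9,2.0,3.4
NM179,NRAS Q61K,12.7,31.1,2.4,59.6,44.2,85.4,1.0,3.3,1.7,6.6
ME4405,NRAS Q61R,60.5,118.2,0.9,0.9,24.0,47.3,1.0,2.1,3.5,14.2
MelAT,NRAS Q61R,31.9,121.3,0.9,1.0,11.8,27.4,1.2,2.0,2.0,10.3
D11M2,NRAS Q61L,11.3,18.4,16.4,33.7,29.2,32.1,1.1,2.4,3.3,9.2
C002M,NRAS Q61K,7.2,31.4,1.0,27.0,13.7,15.6,1.2,2.3,1.4,1.5
C013M,NRAS Q61L,24.7,81.1,1.0,42.7,47.8,199.3,1.0,2.3,2.2,6.5
D38M2,NRAS Q61R,28.6,86.2,4.5,56.5,509.6,480.4,1.1,2.4,2.9,12.2
D22M1,BRAF/NRAS WT,28.0,25.7,1.9,1.9,5.8,5.3,1.3,1.1,1.3,1.2
MeWo,BRAF/NRAS WT,28.9,107.6,1.4,19.1,268.9,176.2,0.9,2.2,1.3,4.2
D24M,BRAF/NRAS WT,32.6,37.2,13.8,43.3,30.7,28.3,1.2,3.3,7.3,31.0
C022M1,BRAF/NRAS WT,10.7,41.7,2.3,21.5,148.3,341.0,1.9,1.6,1.1,1.8
C084M,BRAF/NRAS WT,83.6,119.0,19.5,130.4,552.5,631.5,0.9,4.6,3.2,15.7
C086M,BRAF/NRAS WT,20.1,52.4,22.7,90.3,1.3,2.9,1.1,3.0,3.7,9.9
D35,BRAF/NRAS WT,167.9,460.2,3.8,129.6,21.9,36.9,0.9,2.9,0.9,2.7
C025M1,BRAF/NRAS WT,73.2,134.1,2.1,18.5,1.7,2.7,1.1,2.7,1.1,1.2
SMU15-0217,BRAF/NRAS WT,1.5,2.1,12.8,91.4,11.0,26.0,1.2,3.4,4.4,22.3
A04-GEH,BRAF/NRAS WT,23.9,96.6,1.5,63.3,13.8,45.9,1.0,2.9,1.2,8.2
92.1,GNAQ Q209L,11.5,87.2,0.5,0.5,14.0,38.8,1.1,1.7,1.2,1.0
MEL202,GNAQ Q209L R210K,38.2,346.3,1.1,15.9,10.6,15.0,1.0,5.6,1.0,2.7
MEL270,GNAQ Q209P,52.5,115.6,1.1,1.8,3.6,4.1,1.1,1.6,1.2,1.3
MP38,GNAQ Q209P,73.5,329.7,1.6,10.6,10.6,15.8,1.1,2.4,2.9,25.3
OMM1,GNA11 Q209L,31.2,108.0,1.1,19.0,2.0,3.6,1.1,1.5,1.0,3.7
MP41,GNA11 Q209L,26.3,44.2,0.9,3.7,2.6,3.6,0.9,1.3,1.1,2.0
MP46,GNAQ Q209L,2.3,38.6,1.0,1.0,5.2,10.6,1.1,1.5,1.0,1.6
MM28,GNA11 Q209L,9.4,50.8,1.1,13.1,1.3,1.7,1.0,2.1,1.0,2.1
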