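cell_line,driver_mutation,subg1_pre,subg1_post,g1_pre,g1_post,s_pre,s_post,g2_pre,g2_post,reported_effect
A2058,BRAF V600E,0.6,1.3,68.2,63.3,19.2,26.7,12.7,10.1,s_up
SKMel28,BRAF V600E,1.7,3.8,72.4,73.5,19.6,13.3,8.0,13.3,s_down
C060M1,BRAF V600E,1.1,2.4,72.1,68.2,12.1,11.9,16.1,19.9,
SCC14-0257,BRAF V600K,1.6,5.3,63.4,50.5,20.0,26.1,16.6,23.4,s_up
MM418,BRAF V600E,0.9,9.5,61.8,54.9,24.8,32.4,13.4,12.7,s_up
NM16,BRAF V600E,0.8,4.1,65.6,70.1,26.3,26.8,8.1,3.1,
NM182,BRAF V600E,2.5,4.1,60.8,56.3,28.4,34.8,10.8,8.9,
MM200,BRAF V600E,1.1,17.1,69.9,62.2,19.9,31.1,10.2,6.7,subg1_up+s_up
NM39,BRAF V600E,0.7,2.3,85.2,86.4,9.7,9.8,5.0,3.8,
HT144,BRAF V600E,1.6,12.9,65.4,61.7,24.3,24.4,10.4,13.9,subg1_up
C016M,BRAF V600E,4.0,6.8,73.2,65.4,19.8,22.9,7.0,11.7,
MelRm,NRAS Q61R,0.7,4.1,62.9,64.9,26.8,24.2,10.3,10.8,
NM47,NRAS Q61R,0.4,6.5,63.0,65.3,25.8,24.3,11.2,10.4,
NM177,NRAS Q61R,2.6,2.9,67.6,59.5,23.3,28.4,9.0,12.2,
NM179,NRAS Q61K,1.7,6.7,60.1,52.5,24.8,32.9,15.0,14.7,s_up
ME4405,NRAS Q61R,0.3,0.7,59.7,63.6,28.2,26.1,12.1,10.2,
MelAT,NRAS Q61R,0.5,0.8,58.2,68.0,29.7,22.7,12.2,9.3,
D11M2,NRAS Q61L,7.8,8.7,41.7,39.7,33.4,28.2,24.9,32.2,
C002M,NRAS Q61K,1.4,2.5,73.3,65.5,17.7,27.0,8.9,7.5,s_up
C013M,NRAS Q61L,19.0,35.5,57.1,54.2,26.4,23.8,16.6,21.9,subg1_up
D38M2,NRAS Q61R,0.7,1.3,65.1,59.9,18.2,21.3,16.7,18.9,
D22M1,BRAF/NRAS WT,1.2,1.2,52.7,50.9,37.9,39.5,9.4,9.5,
MeWo,BRAF/NRAS WT,1.1,1.7,49.2,52.9,25.5,24.1,25.4,22.9,
D24M,BRAF/NRAS WT,nd,nd,nd,nd,nd,nd,nd,nd,nd
C022M1,BRAF/NRAS WT,1.4,4.1,80.2,68.3,11.5,17.6,8.2,14.1,s_up
C084M,BRAF/NRAS WT,0.6,1.2,37.0,37.8,22.5,16.4,40.6,45.8,
C086M,BRAF/NRAS WT,4.7,13.4,50.4,48.8,34.0,25.9,15.6,25.3,
D35M1,BRAF/NRAS WT,0.3,1.3,71.9,72.8,20.7,23.5,7.5,3.7,
C025M1,BRAF/NRAS WT,1.2,1.4,75.5,78.0,17.7,16.1,6.8,5.6,
SMU15-0217,BRAF/NRAS WT,0.6,1.4,69.5,67.5,22.2,21.0,8.3,11.5,
A04-GEH,BRAF/NRAS WT,1.0,7.7,60.0,56.9,25.7,24.7,14.3,18.4,
92.1,GNAQ Q209L,0.7,8.3,60.6,87.0,31.6,10.3,7.9,2.7,s_down
MEL202,GNAQ Q209L R210K,0.4,5.2,57.5,72.8,26.8,17.3,15.7,9.9,s_down
MEL270,GNAQ Q209P,0.8,1.4,68.7,69.9,21.8,20.8,9.5,9.3,
MP38,GNAQ Q209P,0.6,2.2,72.7,88.4,12.0,4.2,15.4,7.4,s_down
OMM1,GNA11 Q209L,1.4,1.4,53.4,52.3,35.8,36.4,10.9,11.4,
MP41,GNA11 Q209L,1.2,4.1,60.7,84.0,28.3,12.1,11.0,3.9,s_down
MP46,GNAQ Q209L,1.2,1.8,28.7,29.1,10.4,10.1,57.3,61.4,
MM28,GNA11 Q209L,0.7,1.2,85.6,92.4,7.1,3.4,7.3,4.3,s_down
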