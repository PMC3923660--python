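mutant,category,ligand,kd_um
wild-type,wild-type,ELA,9.5
wild-type,wild-type,AAG,43
αD26W,Affinity,ELA,0.68
αD26W,Affinity,AAG,1.1
αD26Y,Affinity,ELA,0.46
αD26Y,Affinity,AAG,4.5
αR27W,Affinity,ELA,26
αR27W,Affinity,AAG,62
βL98W,Affinity,ELA,2.9
βL98W,Affinity,AAG,11
βF100W,Affinity,ELA,46
βF100W,Affinity,AAG,83
βT102F,Affinity,ELA,8.9
βT102F,Affinity,AAG,27
αG28I,Specificity,ELA,41
αG28I,Specificity,AAG,36
αG28L,Specificity,ELA,99
αG28L,Specificity,AAG,130
αG28Y,Specificity,ELA,120
αG28Y,Specificity,AAG,110
αR27P,Proline,ELA,12
αR27P,Proline,AAG,46
αG28P,Proline,ELA,60
αG28P,Proline,AAG,340
βA55P,Proline,ELA,8.5
βA55P,Proline,AAG,61
αG28N,Test,ELA,40
αG28N,Test,AAG,86
αY50A,Test,ELA,NB
αY50A,Test,AAG,NB
αG94T,Test,ELA,NB
αG94T,Test,AAG,NB
βF100Y,Test,ELA,100
βF100Y,Test,AAG,160
αD26W/βL98W,Combination,ELA,0.033
αD26W/βL98W,Combination,AAG,0.60
αD26Y/βL98W,Combination,ELA,0.024
αD26Y/βL98W,Combination,AAG,1.7
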