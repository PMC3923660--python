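mutant,ligand,ZF,Ros,ZFMin,RosMin,pep_contacts,ddg
αD26W,ELA,-1.23,-3.50,-2.14,-1.60,E1,-1.56
αD26Y,ELA,-1.28,-1.58,-1.82,-1.00,E1,-1.8
αR27P,ELA,-0.80,0.38,-0.69,0.50,,0.16
αR27W,ELA,-0.18,0.83,-1.06,0.20,,0.6
αG28I,ELA,15.83,8.01,-1.06,-0.30,E1,0.87
αG28L,ELA,38.09,29.33,-1.53,-0.80,E1,1.39
αG28N,ELA,9.50,5.00,0.34,0.10,E1,0.85
αG28P,ELA,5.30,1.29,-0.59,0.80,E1,1.09
αG28Y,ELA,9.21,4.38,-0.92,-0.60,E1,1.52
αY50A,ELA,1.70,1.50,1.63,1.50,I5,NB
αG94T,ELA,1.49,1.94,0.57,1.50,,NB
βA55P,ELA,-0.29,-0.20,-0.23,-0.20,,-0.07
βL98W,ELA,1.10,0.02,-0.70,-0.30,L8,-0.71
βF100W,ELA,3.06,6.30,-0.44,-0.80,A3;G4,0.93
βF100Y,ELA,2.33,2.39,0.81,2.10,G4,1.4
βT102F,ELA,-0.06,-0.46,-1.42,-1.40,I5,-0.04
αD26W,AAG,-1.17,-3.30,-1.84,-0.50,,-2.21
αD26Y,AAG,-1.32,-2.11,-1.72,-0.90,A1,-1.36
αR27P,AAG,-0.84,0.43,-0.61,0.70,,0.02
αR27W,AAG,-0.04,0.37,-1.55,0.00,,0.2
αG28I,AAG,-2.18,-0.67,-1.59,-0.70,A1,-0.12
αG28L,AAG,3.66,2.97,-1.68,-1.20,A1;A2,0.65
αG28N,AAG,0.93,-0.03,-0.18,-0.30,A1;A2,0.39
αG28P,AAG,-1.22,-0.84,-1.17,0.00,A1,1.2
αG28Y,AAG,0.23,3.55,-1.79,0.20,A1,0.53
αY50A,AAG,1.02,0.75,0.95,0.80,,NB
αG94T,AAG,6.89,4.83,1.36,3.40,,NB
βA55P,AAG,-0.29,-0.29,-0.25,0.50,,0.19
βL98W,AAG,-0.25,-0.83,-1.02,-0.40,L7;T8,-0.8
βF100W,AAG,1.33,4.96,-1.01,0.30,I4;I6;T8,0.37
βF100Y,AAG,2.80,2.92,1.61,2.40,I4,0.77
βT102F,AAG,-0.01,-0.13,-0.25,0.80,,-0.29
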