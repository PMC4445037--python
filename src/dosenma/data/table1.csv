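study_id,label,location,treatments,sample_sizes,female_pct,mean_ages,duration_weeks,followup_weeks,randomised,concealment,blinding,withdrawal,quality_score,combined_from
Williams2000,Williams 2000,knee,C100BID;C200QD;PBO,231;223;232,67;66;67,63;63;63,6,2;6,1,2,2,1,6,1
Williams2001,Williams 2001,knee,C100BID;C200QD;PBO,243;231;244,69;69;73,62;61;61,6,2;6,1,2,2,1,6,1
Bensen1999,Bensen 1999,knee,C100BID;PBO,197;203,73;75,62;62,12,2;6;12,2,2,2,1,7,1
Conaghan2013,Conaghan 2013,knee,C100BID;PBO,233;227,67;66,61;62,12,2;6;9;12,2,2,2,1,7,1
McKenna2001,McKenna 2001,knee,C100BID;PBO,201;200,68;66,62;60,6,2;6,1,0,1,1,3,1
Rother2007,Rother 2007,knee,C100BID;PBO,132;127,62;63,62;63,6,2;4;6,2,0,1,1,4,1
Zhao1999,Zhao 1999,knee,C100BID;PBO,197;204,73;75,62;62,12,2;6;12,1,0,1,1,3,1
Bingham2007a,Bingham 2007 (1),knee_or_hip,C200QD;PBO,241;127,70;65,63;63,12,2;4;8;12,1,0,2,1,4,1
Bingham2007b,Bingham 2007 (2),knee_or_hip,C200QD;PBO,247;117,62;65,62;61,12,2;4;8;12,1,0,2,1,4,1
Clegg2006,Clegg 2006,knee,C200QD;PBO,318;313,67;64,59;58,24,4;8;16;24,2,0,2,1,5,1
DeLemos2011,DeLemos 2011,knee_or_hip,C200QD;PBO,202;200,65;69,60;59,12,1;2;3;6;9;12,1,2,2,1,6,1
Fleischmann2006,Fleischmann 2006,knee,C200QD;PBO,444;231,67;66,61;62,13,2;4;8;13,1,0,2,1,4,1
Hochberg2011a,Hochberg 2011 (1),knee,C200QD;PBO,242;124,61;66,62;62,12,6;12,2,0,2,1,5,1
Hochberg2011b,Hochberg 2011 (2),knee,C200QD;PBO,244;122,63;63,62;62,12,6;12,2,0,2,1,5,1
Kivitz2001,Kivitz 2001,hip,C200QD;PBO,207;218,65;67,62;64,12,2;6;12,2,0,2,1,5,1
Lehmann2005,Lehmann 2005,knee,C200QD;PBO,420;424,68;72,63;62,13,2;4;13,2,0,2,1,5,1
Lisse2001,Lisse 2001,knee_or_hip,C200QD;PBO,191;188,68;66,75;74,12,2;12,1,0,1,1,3,3
Schnitzer2011,Schnitzer 2011,hip,C200QD;PBO,419;416,61;61,62;61,13,4;8;13,2,2,2,1,7,1
Sheldon2005,Sheldon 2005,knee,C200QD;PBO,393;382,63;61,60;61,13,2;4;8;13,1,0,2,1,4,1
Smugar2006a,Smugar 2006 (1),knee_or_hip,C200QD;PBO,456;150,68;69,62;62,6,2;4;6,1,0,1,1,3,1
Smugar2006b,Smugar 2006 (2),knee_or_hip,C200QD;PBO,460;151,66;68,62;63,6,2;4;6,1,0,1,1,3,1
Tannenbaum2004,Tannenbaum 2004,knee,C200QD;PBO,481;243,69;67,64;65,13,2;4;8;13,1,0,2,1,4,1
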