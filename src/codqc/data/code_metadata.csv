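code_pattern,usability,broad_group,icd_error_category,severity_level,package,redistribution_targets
A00-A39,usable,group1,,,,
A40-A41,unusable,,3,1,sepsis,group1;group2;group3
A42-A99,usable,group1,,,,
B00-B99,usable,group1,,,,
C00-C75,usable,group2,,,,
C76,insufficiently_specified,,5,3,cancer_unspecified,group2
C77-C79,usable,group2,,,,
C80,insufficiently_specified,,5,3,cancer_unspecified,group2
C81-C99,usable,group2,,,,
D00-D64,usable,group2,,,,
D65,unusable,,3,1,sepsis,group1;group2;group3
D66-D99,usable,group2,,,,
E00-E39,usable,group2,,,,
E40-E46,usable,group1,,,,
E47-E85,usable,group2,,,,
E86,unusable,,3,2,volume_depletion,group1;group2
E87-E99,usable,group2,,,,
F00-F99,usable,group2,,,,
G00-G99,usable,group2,,,,
H00-H99,usable,group2,,,,
I00-I09,usable,group2,,,,
I10,unusable,,2,2,hypertension,group2
I11-I45,usable,group2,,,,
I46,unusable,,4,1,cardiac_arrest,group1;group2;group3
I47-I49,usable,group2,,,,
I50,unusable,,3,2,heart_failure,group2
I51-I63,usable,group2,,,,
I64,insufficiently_specified,,5,4,stroke_unspecified,group2
I65-I99,usable,group2,,,,
J00-J22,usable,group1,,,,
J23-J95,usable,group2,,,,
J96,unusable,,4,2,respiratory_failure,group1;group2
J97-J99,usable,group2,,,,
K00-K99,usable,group2,,,,
L00-L99,usable,group2,,,,
M00-M99,usable,group2,,,,
N00-N99,usable,group2,,,,
O00-O99,usable,group1,,,,
P00-P99,usable,group1,,,,
Q00-Q99,usable,group2,,,,
R00-R01,unusable,,1,1,ill_defined,group1;group2;group3
R02,unusable,,3,1,sepsis,group1;group2;group3
R03-R99,unusable,,1,1,ill_defined,group1;group2;group3
S00-S99,usable,group3,,,,
T00-T99,usable,group3,,,,
V00-V99,usable,group3,,,,
W00-W99,usable,group3,,,,
X00-X58,usable,group3,,,,
X59,insufficiently_specified,,5,3,injury_unspecified,group3
X60-X99,usable,group3,,,,
Y00-Y09,usable,group3,,,,
Y10-Y34,unusable,,2,3,undetermined_intent,group3
Y35-Y99,usable,group3,,,,
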