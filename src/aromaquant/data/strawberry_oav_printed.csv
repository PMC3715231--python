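compound,group,day,oav
Methyl acetate,ester,0,0.64
Methyl acetate,ester,1,0.63
Methyl acetate,ester,3,11.52
Methyl acetate,ester,6,0.000255
Methyl acetate,ester,9,0.000122
Ethyl acetate,ester,0,1.82
Ethyl acetate,ester,1,1.63
Ethyl acetate,ester,3,51.3
Ethyl acetate,ester,6,0.05
Ethyl acetate,ester,9,0.00449
Methyl propionate,ester,0,0.42
Methyl propionate,ester,1,0.52
Methyl propionate,ester,3,0.24
Methyl propionate,ester,6,0.00178
S-Methyl thioacetate,ester,0,58.6
S-Methyl thioacetate,ester,1,80.4
Isopropyl acetate,ester,0,0.02
Isopropyl acetate,ester,1,0.01
Isopropyl acetate,ester,3,0.01
Ethyl propionate,ester,0,7.53
Ethyl propionate,ester,3,7.65
Propyl acetate,ester,3,0.19
Propyl acetate,ester,6,0.000754
Methyl butyrate,ester,0,168.0
Methyl butyrate,ester,1,195.0
Methyl butyrate,ester,3,12.5
Methyl butyrate,ester,6,0.07
Methyl 2-methylbutanoate,ester,0,218.0
Methyl 2-methylbutanoate,ester,1,217.0
Methyl 2-methylbutanoate,ester,3,132.0
Methyl 2-methylbutanoate,ester,6,10.86
Isobutyl acetate,ester,0,0.02
Isobutyl acetate,ester,1,0.01
Isobutyl acetate,ester,3,0.19
Isobutyl acetate,ester,6,0.00388
Methyl isovalerate,ester,0,24.9
Methyl isovalerate,ester,1,25.9
Methyl isovalerate,ester,3,3.54
Ethyl butyrate,ester,0,6160.0
Ethyl butyrate,ester,1,4576.0
Ethyl butyrate,ester,3,686.0
Ethyl butyrate,ester,6,6.0
Butyl acetate,ester,0,0.18
Butyl acetate,ester,1,0.19
Butyl acetate,ester,3,0.14
Butyl acetate,ester,6,0.000256
Isopropyl butyrate,ester,0,4.95
Isopropyl butyrate,ester,1,4.18
Ethyl 2-methylbutyrate,ester,0,942.0
Ethyl 2-methylbutyrate,ester,1,356.0
Ethyl 2-methylbutyrate,ester,3,993.0
Ethyl 2-methylbutyrate,ester,6,46.9
Ethyl isovalerate,ester,0,1592.0
Ethyl isovalerate,ester,1,755.0
Ethyl isovalerate,ester,3,405.0
Ethyl isovalerate,ester,6,7.88
Isoamyl acetate,ester,0,21.4
Isoamyl acetate,ester,1,18.2
Isoamyl acetate,ester,3,43.5
Isoamyl acetate,ester,6,0.32
Ethyl valerate,ester,0,21.9
Ethyl valerate,ester,1,5.19
Methyl hexanoate,ester,0,30.1
Methyl hexanoate,ester,1,11.9
Methyl hexanoate,ester,3,0.73
trans-2-Hexenyl acetate,ester,0,0.9
trans-2-Hexenyl acetate,ester,1,0.04
Ethyl hexanoate,ester,0,3608.0
Ethyl hexanoate,ester,1,683.0
Ethyl hexanoate,ester,3,103.7
Ethyl hexanoate,ester,6,0.14
Hexyl acetate,ester,0,54.7
Hexyl acetate,ester,1,12.7
Hexyl acetate,ester,3,2.34
Methyl octanoate,ester,0,0.16
Methyl octanoate,ester,1,0.02
Ethyl alcohol,alcohol,3,0.01
Ethyl alcohol,alcohol,6,1.69
Ethyl alcohol,alcohol,9,0.05
Isopropyl alcohol,alcohol,0,0.000337
Isopropyl alcohol,alcohol,1,0.000176
Isopropyl alcohol,alcohol,3,0.00174
Isopropyl alcohol,alcohol,6,0.00357
Isopropyl alcohol,alcohol,9,0.01
n-Propyl alcohol,alcohol,3,0.01
n-Propyl alcohol,alcohol,6,0.02
n-Propyl alcohol,alcohol,9,0.02
Isobutyl alcohol,alcohol,3,0.04
Isobutyl alcohol,alcohol,6,114.0
Isobutyl alcohol,alcohol,9,0.38
Isopropenylethyl alcohol,alcohol,6,0.000964
Isopropenylethyl alcohol,alcohol,9,0.00179
3-Methyl-1-butanol,alcohol,0,0.02
3-Methyl-1-butanol,alcohol,1,0.03
3-Methyl-1-butanol,alcohol,3,1.13
3-Methyl-1-butanol,alcohol,6,0.6
3-Methyl-1-butanol,alcohol,9,0.97
2-Methyl-1-butanol,alcohol,6,0.23
2-Methyl-1-butanol,alcohol,9,0.48
n-Pentanol,alcohol,6,0.00212
n-Pentanol,alcohol,9,0.00184
1-Chloro-2-propanol,alcohol,0,0.02
1-Chloro-2-propanol,alcohol,1,0.08
n-Hexanol,alcohol,0,0.01
n-Hexanol,alcohol,3,0.03
n-Hexanol,alcohol,6,0.00345
n-Hexanol,alcohol,9,0.02
Linalool,alcohol,0,27.4
Linalool,alcohol,1,27.0
Acetaldehyde,aldehyde,0,8.7
Acetaldehyde,aldehyde,1,8.85
Acetaldehyde,aldehyde,3,56.9
Acetaldehyde,aldehyde,6,3.92
Acetaldehyde,aldehyde,9,2.9
Allyl aldehyde (Acrolein),aldehyde,6,0.03
Allyl aldehyde (Acrolein),aldehyde,9,0.04
Methylacryl aldehyde,aldehyde,6,0.21
Methylacryl aldehyde,aldehyde,9,0.39
Isobutyraldehyde,aldehyde,6,0.01
Isobutyraldehyde,aldehyde,9,0.09
Isovaleraldehyde,aldehyde,6,0.46
Isovaleraldehyde,aldehyde,9,1.09
Acetone,ketone,0,0.06
Acetone,ketone,1,0.07
Acetone,ketone,3,0.00534
Acetone,ketone,6,0.000175
Acetone,ketone,9,0.000668
Methyl ethyl ketone,ketone,6,0.000148
Methyl ethyl ketone,ketone,9,0.000173
Methyl n-propyl ketone,ketone,0,0.03
Methyl n-propyl ketone,ketone,1,0.03
Methyl isobutyl ketone,ketone,0,0.01
Methyl isobutyl ketone,ketone,1,0.01
Methyl isobutyl ketone,ketone,3,0.00206
Methyl amyl ketone,ketone,0,0.04
Methyl amyl ketone,ketone,1,0.05
Methyl amyl ketone,ketone,6,0.0036
Methyl amyl ketone,ketone,9,0.00434
Acetic acid,fatty_acid,0,17.37
Acetic acid,fatty_acid,1,13.23
Acetic acid,fatty_acid,3,12.15
Acetic acid,fatty_acid,6,1.45
Acetic acid,fatty_acid,9,0.6
2-Propynoic acid,fatty_acid,0,0.74
n-Pentane,etc,0,0.000384
n-Pentane,etc,6,9.29e-06
n-Pentane,etc,9,6.97e-05
Ethyl ether,etc,3,0.00212
Ethyl ether,etc,6,0.00123
Ethyl ether,etc,9,0.00439
"1,3-Hexadiene",etc,0,0.01
"1,3-Hexadiene",etc,1,0.000886
n-Hexane,etc,0,5.55e-05
n-Hexane,etc,1,4.67e-05
n-Hexane,etc,3,4.64e-05
n-Hexane,etc,9,0.000367
Toluene,etc,9,0.0016
Styrene,etc,0,0.29
Styrene,etc,1,0.34
Styrene,etc,3,0.55
Styrene,etc,6,0.09
Styrene,etc,9,0.03
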