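name,formula,mw,group,n_C,n_H,n_O,n_carbonyl,n_ether,n_methyl,thresholds,descriptors,is_standard
Methyl acetate,C3H6O2,74.08,ester,3,6,2,1,1,2,6169.88@backsolved,,False
Ethyl acetate,C4H8O2,88.11,ester,4,8,2,1,1,2,2630.97@backsolved,sweet fruit;grape;fruity,False
Methyl propionate,C4H8O2,88.11,ester,4,8,2,1,1,2,95.5056@backsolved,,False
S-Methyl thioacetate,C3H6OS,90.14,ester,3,6,1,1,0,2,1.60821@backsolved,sulfurous;cheesy,False
Isopropyl acetate,C5H10O2,102.13,ester,5,10,2,1,1,3,2640@backsolved,,False
Ethyl propionate,C5H10O2,102.13,ester,5,10,2,1,1,2,6.99346@backsolved,,False
Propyl acetate,C5H10O2,102.13,ester,5,10,2,1,1,2,954.907@backsolved,,False
Methyl butyrate,C5H10O2,102.13,ester,5,10,2,1,1,2,7.09744@backsolved,apple;fruity;cheese,False
Methyl 2-methylbutanoate,C6H12O2,116.16,ester,6,12,2,1,1,3,0.0994475@backsolved,green apple;fruity;sweet,False
Isobutyl acetate,C6H12O2,116.16,ester,6,12,2,1,1,3,479.381@backsolved,strawberry;light fruity;flowery,False
Methyl isovalerate,C6H12O2,116.16,ester,6,12,2,1,1,3,2.19691@backsolved,fruity;apple;pineapple,False
Ethyl butyrate,C6H12O2,116.16,ester,6,12,2,1,1,2,0.249513@backsolved,fruity;sweet;pineapple;strawberry,False
Butyl acetate,C6H12O2,116.16,ester,6,12,2,1,1,2,195.313@backsolved,fruity;banana;apple,True
Isopropyl butyrate,C7H14O2,130.18,ester,7,14,2,1,1,3,6.20202@backsolved,fruity;sweet;pineapple,False
Ethyl 2-methylbutyrate,C7H14O2,130.18,ester,7,14,2,1,1,3,0.0667674@backsolved,sour;cheesy;sweaty;fruity,False
Ethyl isovalerate,C7H14O2,130.18,ester,7,14,2,1,1,3,0.089196@backsolved,fruity;apple;pineapple;sweet fruit,False
Isoamyl acetate,C7H14O2,130.18,ester,7,14,2,1,1,3,3.7931@backsolved,,False
Ethyl valerate,C7H14O2,130.18,ester,7,14,2,1,1,2,0.33379@backsolved,,False
Methyl hexanoate,C7H14O2,130.18,ester,7,14,2,1,1,2,15.5814@backsolved,fruity;pineapple;ester-like,False
trans-2-Hexenyl acetate,C8H14O2,142.2,ester,8,14,2,1,1,2,42.8889@backsolved,,False
Ethyl hexanoate,C8H16O2,144.21,ester,8,16,2,1,1,2,0.200942@backsolved,fruity;sweet;pineapple;green apple,False
Hexyl acetate,C8H16O2,144.21,ester,8,16,2,1,1,2,2.01097@backsolved,fruity;green apple;banana;pear,False
Methyl octanoate,C9H18O2,158.24,ester,9,18,2,1,1,2,36.5@backsolved,sweet fruity,False
Ethyl alcohol,C2H6O,46.07,alcohol,2,6,1,0,0,1,28807.7@backsolved,,False
Isopropyl alcohol,C3H8O,60.1,alcohol,3,8,1,0,0,2,25994.4@backsolved,fruity,False
n-Propyl alcohol,C3H8O,60.1,alcohol,3,8,1,0,0,1,2330@backsolved,sweet (candy),False
Isobutyl alcohol,C4H10O,74.12,alcohol,4,10,1,0,0,2,834.526@backsolved,plastic;bad,True
Isopropenylethyl alcohol,C5H10O,86.13,alcohol,5,10,1,0,0,1,2497.21@backsolved,,False
3-Methyl-1-butanol,C5H12O,88.15,alcohol,5,12,1,0,0,2,44.8673@backsolved,bitter;harsh;fusel oil,False
2-Methyl-1-butanol,C5H12O,88.15,alcohol,5,12,1,0,0,2,40.8333@backsolved,alcoholic;green;fusel oil,False
n-Pentanol,C5H12O,88.15,alcohol,5,12,1,0,0,1,466.981@backsolved,,False
1-Chloro-2-propanol,C3H7ClO,94.54,alcohol,3,7,1,0,0,1,1003.75@backsolved,,False
n-Hexanol,C6H14O,102.17,alcohol,6,14,1,0,0,1,43.4783@backsolved,winey-fruity;green;grass;fresh,False
Linalool,C10H18O,154.25,alcohol,10,18,1,0,0,3,0.187591@backsolved,citrus;fruity;floral;rose,False
Acetaldehyde,C2H4O,44.05,aldehyde,2,4,1,1,0,1,186.011@backsolved,green apple;fruity;pungent,True
Allyl aldehyde (Acrolein),C3H4O,56.06,aldehyde,3,4,1,1,0,0,172.5@backsolved,,False
Methylacryl aldehyde,C4H6O,70.09,aldehyde,4,6,1,1,0,1,8.53846@backsolved,,False
Isobutyraldehyde,C4H8O,72.11,aldehyde,4,8,1,1,0,2,42.2222@backsolved,green;malty;floral,False
Isovaleraldehyde,C5H10O,86.13,aldehyde,5,10,1,1,0,2,2.24771@backsolved,green;malty,True
Acetone,C3H6O,58.08,ketone,3,6,1,1,0,2,41947.6@backsolved,aldehydic;wood pulp;hay,False
Methyl ethyl ketone,C4H8O,72.11,ketone,4,8,1,1,0,2,7803.47@backsolved,butter;sweet;chocolate,True
Methyl n-propyl ketone,C5H10O,86.13,ketone,5,10,1,1,0,2,1800@backsolved,thinner;acetone;sweet;fruity,False
Methyl isobutyl ketone,C6H12O,100.16,ketone,6,12,1,1,0,3,538.835@backsolved,,True
Methyl amyl ketone,C7H14O,114.19,ketone,7,14,1,1,0,2,140.553@backsolved,meaty;green;cheese,False
Acetic acid,C2H4O2,60.05,fatty_acid,2,4,2,1,0,1,145.02@backsolved,sour;vinegar,False
2-Propynoic acid,C3H2O2,70.05,fatty_acid,3,2,2,1,0,0,94.0541@backsolved,,False
n-Pentane,C5H12,72.15,etc,5,12,0,0,0,2,31510.4@backsolved,,False
Ethyl ether,C4H10O,74.12,etc,4,10,1,0,1,2,330.296@backsolved,,False
"1,3-Hexadiene",C6H10,82.14,etc,6,10,0,0,0,1,1997.74@backsolved,,False
n-Hexane,C6H14,86.18,etc,6,14,0,0,0,2,21880.1@backsolved,,False
Toluene,C7H8,92.14,etc,7,8,0,0,0,1,1550@backsolved,,True
Styrene,C8H8,104.15,etc,8,8,0,0,0,0,35.2727@backsolved,,True
"2,5-Dimethyl-4-methoxy-3(2H)-furanone",C7H10O3,142.15,etc,7,10,3,1,2,3,,,False
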