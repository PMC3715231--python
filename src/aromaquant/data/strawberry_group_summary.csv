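group,day,n_detected,n_consistent,sum_ugm3
ester,0,47,,52648.0
ester,1,38,34.0,42713.0
ester,3,31,24.0,705447.0
ester,6,18,14.0,533.0
ester,9,4,3.0,45.7
alcohol,0,7,,140.0
alcohol,1,5,4.0,364.0
alcohol,3,8,3.0,1078.0
alcohol,6,17,7.0,379789.0
alcohol,9,16,16.0,4658.0
aldehyde,0,3,,2918.0
aldehyde,1,1,1.0,2959.0
aldehyde,3,3,1.0,19054.0
aldehyde,6,8,2.0,1338.0
aldehyde,9,8,7.0,1022.0
ketone,0,6,,6251.0
ketone,1,4,4.0,7649.0
ketone,3,5,2.0,589.0
ketone,6,5,2.0,35.0
ketone,9,4,4.0,73.9
fatty_acid,0,3,,6390.0
fatty_acid,1,1,1.0,4703.0
fatty_acid,3,1,1.0,4319.0
fatty_acid,6,2,1.0,516.0
fatty_acid,9,2,1.0,212.0
etc,0,15,,221.0
etc,1,12,7.0,115.0
etc,3,7,5.0,105.0
etc,6,15,3.0,35.1
etc,9,21,8.0,73.4
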