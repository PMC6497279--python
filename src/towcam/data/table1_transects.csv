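transect_id,depth_m,frames,shannon_h,hills_n2
Trans1,15.1,563,1.072,2.072
Trans2,22.8,34,0.974,2.462
Trans3,24.4,806,1.223,2.560
Trans4,24.4,35,0.970,2.419
Trans5,26.5,1036,0.587,1.357
Trans6,25.8,1007,0.780,1.559
Trans7,26.8,912,0.576,1.361
All,24.5,4393,1.266,2.917
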