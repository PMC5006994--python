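name,assay_mode,direction,kind,form,a,b,r2
L-Histidine,HILICpos,decreasing,logarithmic,logarithmic,-1e5,1e6,0.8433
Glycerophosphocholine,HILICpos,increasing,linear,linear,188303,-110912,0.9979
Oleoylcarnitine,HILICpos,increasing,power,power,277587,0.4468,0.9854
L-Palmitoylcarnitine,HILICpos,increasing,power,power,170310,0.3882,0.9778
PA(20:1/0:0),HILICpos,increasing,power,power,650494,0.2267,0.9875
PC(16:0/0:0),HILICpos,increasing,power,power,7e7,0.3404,0.9927
PC(O-16:1/0:0),HILICpos,increasing,power,power,155226,0.4488,0.9974
PC(O-18:0/0:0),HILICpos,increasing,power,power,45255,0.5283,0.9852
PC(20:1/0:0),HILICpos,increasing,power,power,162933,0.4378,0.992
PC(20:3/0:0),HILICpos,increasing,power,power,793974,0.2119,0.9851
L-Lactic acid,HILICneg,increasing,power,power,1e7,0.4748,0.9551
Succinic acid,HILICneg,increasing,power,power,20436,0.4232,0.9687
Threonic acid,HILICneg,increasing,power,power,28250,0.3007,0.9223
L-Glyceric acid,HILICneg,increasing,power,power,7518.8,0.1083,0.9673
Ethylphosphate,HILICneg,increasing,power,power,44786,0.4037,0.9601
Beta-Citryl-L-glutamic acid,HILICneg,increasing,power,power,36468,0.3966,0.9608
PA(16:0/0:0),HILICneg,increasing,power,power,97140,0.1932,0.9824
D-Glucose,HILICneg,decreasing,logarithmic,logarithmic,-7e5,3e6,0.9118
D-Ribose,HILICneg,decreasing,logarithmic,logarithmic,-26418,118800,0.9101
Methylsuccinic acid,HILICneg,decreasing,logarithmic,logarithmic,-26854,115962,0.9139
L-Erythrulose,HILICneg,decreasing,logarithmic,logarithmic,-44871,203422,0.9134
Acrylic acid,HILICneg,decreasing,logarithmic,logarithmic,-4460,18760,0.9108
PE(20:4/0:0),HILICneg,decreasing,logarithmic,logarithmic,-21310,93068,0.9872
Hydroxyprolyl-Tyrosine,HILICneg,increasing,linear,linear,64.432,1275.6,0.9765
Tetradecanedioic acid,HILICneg,decreasing,linear,linear,-8354.1,61556,0.9955
PC(O-18:1/0:0),C18pos,increasing,power,power,24044,0.5118,0.9985
PC(14:0/0:0),C18pos,increasing,power,power,40662,0.318,0.9868
PC(18:0/0:0),C18pos,increasing,power,power,99236,0.42,0.9949
PC(O-16:0/0:0),C18pos,increasing,power,power,34731,0.3774,0.9961
PC(16:1/0:0),C18pos,increasing,power,power,119274,0.2217,0.9326
PC(22:6/0:0),C18pos,increasing,power,power,148097,0.1866,0.9653
Allantoic acid,C18pos,increasing,power,power,516.24,0.1803,0.7172
PC(20:4/0:0),C18pos,increasing,power,power,118726,0.192,0.9901
PC(0:0/20:4),C18pos,increasing,power,power,1944.8,0.1386,0.9666
PA(20:4/0:0),C18pos,increasing,power,power,2000.7,0.0771,0.8869
L-Glutamic acid,C18neg,increasing,linear,linear,33.032,200.84,0.9867
Taurine,C18neg,increasing,linear,linear,103.39,1543.5,0.9317
Uric acid,C18neg,decreasing,logarithmic,linear,256.13,1575.8,0.9919
Ribonic acid,C18neg,increasing,linear,logarithmic,-22623,98337,0.9283
Aspartyl-Cysteine,C18neg,decreasing,logarithmic,logarithmic,-18480,249512,0.7661
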