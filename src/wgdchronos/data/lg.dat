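   0.425093 
   0.276818    0.751878 
   0.395144    0.123954    5.076149 
   2.489084    0.534551    0.528768    0.062556 
   0.969894    2.807908    1.695752    0.523386    0.084808 
   1.038545     0.36397    0.541712     5.24387    0.003499    4.128591 
    2.06604    0.390192    1.437645    0.844926    0.569265    0.267959    0.348847 
   0.358858    2.426601    4.509238    0.927114    0.640543    4.813505    0.423881    0.311484 
    0.14983    0.126991    0.191503     0.01069    0.320627    0.072854    0.044265    0.008705    0.108882 
   0.395337    0.301848    0.068427    0.015076    0.594007    0.582457    0.069673    0.044261    0.366317    4.145067 
   0.536518    6.326067    2.145078    0.282959    0.013266    3.234294    1.807177    0.296636    0.697264    0.159069      0.1375 
   1.124035    0.484133    0.371004    0.025548     0.89368    1.672569    0.173735    0.139538    0.442472    4.273607    6.312358    0.656604 
   0.253701    0.052722    0.089525    0.017416    1.105251    0.035855    0.018811    0.089586    0.682139    1.112727    2.592692    0.023918    1.798853 
   1.177651    0.332533    0.161787    0.394456    0.075382    0.624294    0.419409    0.196961    0.508851    0.078281     0.24906    0.390322    0.099849    0.094464 
   4.727182    0.858151    4.008358    1.240275    2.784478    1.223828    0.611973     1.73999    0.990012    0.064105    0.182287    0.748683     0.34696    0.361819    1.338132 
   2.139501    0.578987    2.000679     0.42586     1.14348    1.080136    0.604545    0.129836    0.584262    1.033739    0.302936    1.136863    2.020366    0.165001    0.571468    6.472279 
   0.180717    0.593607    0.045376     0.02989    0.670128    0.236199    0.077852    0.268491    0.597054     0.11166    0.619632    0.049906    0.696175    2.457121    0.095131    0.248862    0.140825 
   0.218959     0.31444    0.612025    0.135107    1.165532    0.257336    0.120037    0.054679    5.306834    0.232523    0.299648    0.131932    0.481306    7.803902    0.089613    0.400547    0.245841    3.151815 
    2.54787    0.170887    0.083688    0.037967    1.959291    0.210332    0.245034    0.076701    0.119013   10.649107    1.702745    0.185202    1.898718    0.654683    0.296501    0.098369    2.188158     0.18951    0.249313 

0.07906592093 0.05594094406 0.04197695802 0.05305194695 0.01293698706 0.04076695923 0.07158592841 0.05733694266 0.02235497765 0.06215693784 0.09908090092 0.0645999354 0.02295097705 0.0423019577 0.04403995596 0.0611969388 0.05328694671 0.01206598793 0.03415496585 0.06914693085 
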