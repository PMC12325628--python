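Age (years),Mean Fiber Diameter (um),Fiber Count,Elastin Volume Fraction (%),Number of Fiber Clusters,Maximum Cluster Size,Vertical Fiber Proportion (%),Normalized Skin Firmness
38,3.86,2437,4.23,5,2415,25.44,1.0
39,3.54,1060,2.34,17,795,28.30,0.155
43,3.68,2183,5.26,11,2127,18.51,0.837
49,3.59,2056,3.26,28,1642,32.48,0.533
58,3.45,2081,4.18,32,1883,26.86,0.301
59,3.52,1713,3.63,19,1070,16.40,0.318
67,3.35,804,2.28,47,248,6.22,0.0256
70,3.37,1352,2.25,40,626,17.31,0.044
78,3.36,1070,2.32,51,303,9.63,0.0
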