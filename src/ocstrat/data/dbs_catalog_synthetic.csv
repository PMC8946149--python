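Type,DBS2,DBS4,DBS5,DBS7,DBS11
AC>CA,0.03048486,0.00012821,0.00012821,0.00012821,0.00012821
AC>CG,0.00017209,0.00012821,0.00012821,0.00012821,0.00012821
AC>CT,0.00012821,0.03684314,0.00012821,0.00012821,0.00012821
AC>GA,0.00012821,0.00012821,0.00012821,0.00012821,0.00090792
AC>GG,0.09964704,0.00012821,0.00012821,0.00012821,0.00012821
AC>GT,0.00012821,0.00012821,0.28562637,0.00012821,0.00012821
AC>TA,0.00012821,0.00012821,0.00012821,0.00012821,0.14461484
AC>TG,0.00012821,0.00012821,0.04204053,0.00012821,0.00012821
AC>TT,0.00012821,0.08056209,0.00012821,0.00012821,0.00012821
AT>CA,0.00012821,0.03299818,0.00012821,0.00012821,0.00012821
AT>CC,0.00012821,0.00012821,0.00085637,0.00012821,0.00012821
AT>CG,0.00012821,0.00012821,0.00012821,0.03720721,0.00012821
AT>GA,0.02670011,0.00012821,0.00012821,0.00012821,0.00012821
AT>GC,0.13263253,0.00012821,0.00012821,0.00012821,0.00012821
AT>TA,0.00012821,0.00509602,0.00012821,0.00012821,0.00012821
CC>AA,0.00012821,0.00012821,0.00012821,0.00012821,0.01642546
CC>AG,0.00012821,0.00012821,0.02742015,0.00012821,0.00012821
CC>AT,0.00012821,0.08001266,0.00012821,0.00012821,0.00012821
CC>GA,0.00012821,0.00012821,0.00012821,0.10297167,0.00012821
CC>GG,0.00012821,0.11166515,0.00012821,0.00012821,0.00012821
CC>GT,0.00012821,0.00012821,0.00012821,0.06878351,0.00012821
CC>TA,0.00012821,0.00012821,0.00012821,0.03077512,0.00012821
CC>TG,0.00012821,0.03442779,0.00012821,0.00012821,0.00012821
CC>TT,0.00012821,0.00012821,0.00012821,0.00012821,0.00199469
CG>AA,0.00012821,0.00012821,0.02586473,0.00012821,0.00012821
CG>AC,0.00012821,0.00012821,0.00012821,0.11648596,0.00012821
CG>AT,0.00012821,0.00012821,0.00012821,0.00986019,0.00012821
CG>GA,0.00012821,0.00012821,0.01335163,0.00012821,0.00012821
CG>GC,0.00012821,0.00012821,0.00012821,0.05109156,0.00012821
CG>TA,0.04691213,0.00012821,0.00012821,0.00012821,0.00012821
CT>AA,0.00012821,0.00012821,0.00012821,0.00012821,0.06456372
CT>AC,0.00012821,0.00012821,0.00012821,0.00012821,0.07263963
CT>AG,0.00012821,0.04853975,0.00012821,0.00012821,0.00012821
CT>GA,0.00012821,0.00012821,0.00012821,0.02925743,0.00012821
CT>GC,0.00012821,0.00906303,0.00012821,0.00012821,0.00012821
CT>GG,0.00012821,0.00012821,0.00012821,0.00012821,0.0371918
CT>TA,0.00012821,0.00012821,0.0007146,0.00012821,0.00012821
CT>TC,0.00012821,0.02945314,0.00012821,0.00012821,0.00012821
CT>TG,0.02819798,0.00012821,0.00012821,0.00012821,0.00012821
GC>AA,0.15513816,0.00012821,0.00012821,0.00012821,0.00012821
GC>AG,0.00012821,0.00012821,0.00104652,0.00012821,0.00012821
GC>AT,0.00012821,0.00012821,0.09416833,0.00012821,0.00012821
GC>CA,0.03274441,0.00012821,0.00012821,0.00012821,0.00012821
GC>CG,0.00121669,0.00012821,0.00012821,0.00012821,0.00012821
GC>TA,0.00012821,0.00012821,0.00012821,0.00012821,0.01495771
TA>AC,0.00012821,0.00012821,0.02295997,0.00012821,0.00012821
TA>AG,0.00012821,0.00012821,0.00012821,0.17226806,0.00012821
TA>AT,0.00012821,0.00012821,0.03063203,0.00012821,0.00012821
TA>CC,0.00012821,0.00141081,0.00012821,0.00012821,0.00012821
TA>CG,0.0074645,0.00012821,0.00012821,0.00012821,0.00012821
TA>GC,0.00012821,0.00012821,0.00012821,0.19213813,0.00012821
TC>AA,0.00012821,0.00012821,0.00012821,0.00012821,0.00817354
TC>AG,0.16059394,0.00012821,0.00012821,0.00012821,0.00012821
TC>AT,0.00012821,0.00012821,0.00012821,0.00012821,0.00017568
TC>CA,0.00012821,0.00262984,0.00012821,0.00012821,0.00012821
TC>CG,0.00012821,0.00012821,0.00012821,0.01493641,0.00012821
TC>CT,0.00012821,0.00012821,0.00012821,0.00012821,0.00120233
TC>GA,0.00012821,0.16712123,0.00012821,0.00012821,0.00012821
TC>GG,0.13527773,0.00012821,0.00012821,0.00012821,0.00012821
TC>GT,0.00012821,0.00012821,0.00012821,0.10498405,0.00012821
TG>AA,0.00012821,0.00012821,0.16823292,0.00012821,0.00012821
TG>AC,0.00012821,0.00012821,0.00012821,0.05165303,0.00012821
TG>AT,0.00012821,0.00012821,0.00012821,0.00072018,0.00012821
TG>CA,0.00012821,0.00012821,0.00012821,0.00012821,0.00291241
TG>CC,0.00012821,0.00012821,0.00012821,0.00012821,0.085306
TG>CT,0.00012821,0.00012821,0.00012821,0.00879059,0.00012821
TG>GA,0.00012821,0.00012821,0.1483807,0.00012821,0.00012821
TG>GC,0.00012821,0.0922817,0.00012821,0.00012821,0.00012821
TG>GT,0.00012821,0.00570893,0.00012821,0.00012821,0.00012821
TT>AA,0.00012821,0.00012821,0.00012821,0.00012821,0.50334011
TT>AC,0.00012821,0.00012821,0.01857372,0.00012821,0.00012821
TT>AG,0.00012821,0.00012821,0.00012821,0.00012821,0.03751723
TT>CA,0.06663648,0.00012821,0.00012821,0.00012821,0.00012821
TT>CC,0.00012821,0.00012821,0.02344998,0.00012821,0.00012821
TT>CG,0.0659947,0.00012821,0.00012821,0.00012821,0.00012821
TT>GA,0.00012821,0.25423782,0.00012821,0.00012821,0.00012821
TT>GC,0.00223795,0.00012821,0.00012821,0.00012821,0.00012821
TT>GG,0.00012821,0.00012821,0.08873274,0.00012821,0.00012821
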