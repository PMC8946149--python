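Type,ID1,ID2,ID5,ID6,ID8
1:Del:C:1,0.00012048,0.113337,0.00012048,0.00012048,0.00012048
1:Del:C:2,0.00012048,0.07716119,0.00012048,0.00012048,0.00012048
1:Del:C:3,0.00012048,0.03506613,0.00012048,0.00012048,0.00012048
1:Del:C:4,0.00012048,0.15270623,0.00012048,0.00012048,0.00012048
1:Del:C:5,0.00012048,0.1061217,0.00012048,0.00012048,0.00012048
1:Del:C:6,0.00012048,0.11892502,0.00012048,0.00012048,0.00012048
1:Del:T:1,0.00012048,0.09654662,0.00012048,0.00012048,0.00012048
1:Del:T:2,0.00012048,0.04976057,0.00012048,0.00012048,0.00012048
1:Del:T:3,0.00012048,0.11367816,0.00012048,0.00012048,0.00012048
1:Del:T:4,0.00012048,0.07826237,0.00012048,0.00012048,0.00012048
1:Del:T:5,0.00012048,0.02780549,0.00012048,0.00012048,0.00012048
1:Del:T:6,0.00012048,0.0220753,0.00012048,0.00012048,0.00012048
1:Ins:C:0,0.00686363,0.00012048,0.00012048,0.00012048,0.00012048
1:Ins:C:1,0.17573265,0.00012048,0.00012048,0.00012048,0.00012048
1:Ins:C:2,0.01080416,0.00012048,0.00012048,0.00012048,0.00012048
1:Ins:C:3,0.00371394,0.00012048,0.00012048,0.00012048,0.00012048
1:Ins:C:4,0.12237167,0.00012048,0.00012048,0.00012048,0.00012048
1:Ins:C:5,0.0214497,0.00012048,0.00012048,0.00012048,0.00012048
1:Ins:T:0,0.25572249,0.00012048,0.00012048,0.00012048,0.00012048
1:Ins:T:1,0.07889591,0.00012048,0.00012048,0.00012048,0.00012048
1:Ins:T:2,0.03198385,0.00012048,0.00012048,0.00012048,0.00012048
1:Ins:T:3,0.07919086,0.00012048,0.00012048,0.00012048,0.00012048
1:Ins:T:4,0.15142063,0.00012048,0.00012048,0.00012048,0.00012048
1:Ins:T:5,0.0532963,0.00012048,0.00012048,0.00012048,0.00012048
2:Del:R:1,0.00012048,0.00012048,0.00012048,0.00012048,0.00521762
2:Del:R:2,0.00012048,0.00012048,0.00012048,0.00012048,0.03872113
2:Del:R:3,0.00012048,0.00012048,0.00012048,0.00012048,0.02381642
2:Del:R:4,0.00012048,0.00012048,0.00012048,0.00012048,0.06406098
2:Del:R:5,0.00012048,0.00012048,0.00012048,0.00012048,0.00630751
2:Del:R:6,0.00012048,0.00012048,0.00012048,0.00012048,0.02032166
3:Del:R:1,0.00012048,0.00012048,0.00012048,0.00012048,0.00012048
3:Del:R:2,0.00012048,0.00012048,0.00012048,0.00012048,0.00012048
3:Del:R:3,0.00012048,0.00012048,0.00012048,0.00012048,0.00012048
3:Del:R:4,0.00012048,0.00012048,0.00012048,0.00012048,0.00012048
3:Del:R:5,0.00012048,0.00012048,0.00012048,0.00012048,0.00012048
3:Del:R:6,0.00012048,0.00012048,0.00012048,0.00012048,0.00012048
4:Del:R:1,0.00012048,0.00012048,0.00012048,0.00012048,0.00012048
4:Del:R:2,0.00012048,0.00012048,0.00012048,0.00012048,0.00012048
4:Del:R:3,0.00012048,0.00012048,0.00012048,0.00012048,0.00012048
4:Del:R:4,0.00012048,0.00012048,0.00012048,0.00012048,0.00012048
4:Del:R:5,0.00012048,0.00012048,0.00012048,0.00012048,0.00012048
4:Del:R:6,0.00012048,0.00012048,0.00012048,0.00012048,0.00012048
5:Del:R:1,0.00012048,0.00012048,0.00012048,0.00012048,0.00381534
5:Del:R:2,0.00012048,0.00012048,0.00012048,0.00012048,0.02991654
5:Del:R:3,0.00012048,0.00012048,0.00012048,0.00012048,0.0772917
5:Del:R:4,0.00012048,0.00012048,0.00012048,0.00012048,0.01011868
5:Del:R:5,0.00012048,0.00012048,0.00012048,0.00012048,0.05745031
5:Del:R:6,0.00012048,0.00012048,0.00012048,0.00012048,0.11389726
2:Ins:R:0,0.00012048,0.00012048,0.00023687,0.00012048,0.00012048
2:Ins:R:1,0.00012048,0.00012048,0.02730839,0.00012048,0.00012048
2:Ins:R:2,0.00012048,0.00012048,0.09167598,0.00012048,0.00012048
2:Ins:R:3,0.00012048,0.00012048,0.07050504,0.00012048,0.00012048
2:Ins:R:4,0.00012048,0.00012048,0.0006531,0.00012048,0.00012048
2:Ins:R:5,0.00012048,0.00012048,0.00258271,0.00012048,0.00012048
3:Ins:R:0,0.00012048,0.00012048,0.02588856,0.00012048,0.00012048
3:Ins:R:1,0.00012048,0.00012048,0.05115492,0.00012048,0.00012048
3:Ins:R:2,0.00012048,0.00012048,0.00904338,0.00012048,0.00012048
3:Ins:R:3,0.00012048,0.00012048,0.15816543,0.00012048,0.00012048
3:Ins:R:4,0.00012048,0.00012048,0.05203177,0.00012048,0.00012048
3:Ins:R:5,0.00012048,0.00012048,0.07412008,0.00012048,0.00012048
4:Ins:R:0,0.00012048,0.00012048,0.08011039,0.00012048,0.00012048
4:Ins:R:1,0.00012048,0.00012048,0.06497043,0.00012048,0.00012048
4:Ins:R:2,0.00012048,0.00012048,0.00453598,0.00012048,0.00012048
4:Ins:R:3,0.00012048,0.00012048,0.01832699,0.00012048,0.00012048
4:Ins:R:4,0.00012048,0.00012048,0.1416773,0.00012048,0.00012048
4:Ins:R:5,0.00012048,0.00012048,0.00016822,0.00012048,0.00012048
5:Ins:R:0,0.00012048,0.00012048,0.04072969,0.00012048,0.00012048
5:Ins:R:1,0.00012048,0.00012048,0.02465934,0.00012048,0.00012048
5:Ins:R:2,0.00012048,0.00012048,0.00327362,0.00012048,0.00012048
5:Ins:R:3,0.00012048,0.00012048,0.02463052,0.00012048,0.00012048
5:Ins:R:4,0.00012048,0.00012048,0.01235574,0.00012048,0.00012048
5:Ins:R:5,0.00012048,0.00012048,0.01408713,0.00012048,0.00012048
2:Del:M:1,0.00012048,0.00012048,0.00012048,0.00012048,0.24498525
3:Del:M:1,0.00012048,0.00012048,0.00012048,0.05970039,0.00012048
3:Del:M:2,0.00012048,0.00012048,0.00012048,0.02653232,0.00012048
4:Del:M:1,0.00012048,0.00012048,0.00012048,0.04587745,0.00012048
4:Del:M:2,0.00012048,0.00012048,0.00012048,0.0241751,0.00012048
4:Del:M:3,0.00012048,0.00012048,0.00012048,0.12535077,0.00012048
5:Del:M:1,0.00012048,0.00012048,0.00012048,0.24524144,0.02064331
5:Del:M:2,0.00012048,0.00012048,0.00012048,0.20172304,0.05837572
5:Del:M:3,0.00012048,0.00012048,0.00012048,0.02678601,0.07381363
5:Del:M:4,0.00012048,0.00012048,0.00012048,0.15975283,0.12103074
5:Del:M:5,0.00012048,0.00012048,0.00012048,0.07606547,0.02238488
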