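barcode,birth_year,sex,sexmk_1,sexmk_2,BM1824_1,BM1824_2,BM2113_1,BM2113_2,ETH10_1,ETH10_2,ETH225_1,ETH225_2,ETH3_1,ETH3_2,INRA023_1,INRA023_2,SPS115_1,SPS115_2,TGLA122_1,TGLA122_2,TGLA126_1,TGLA126_2,TGLA227_1,TGLA227_2,TGLA53_1,TGLA53_2
H0006319,2020,M,X,Y,178,178,122,122,209,221,152,156,107,131,205,205,248,260,190,190,123,123,91,103,180,182
H0004699,2019,F,X,X,178,188,122,122,223,223,150,150,125,131,203,205,248,262,138,142,117,123,95,109,176,182
H0006302,2020,F,X,X,178,194,122,122,213,223,152,154,125,127,205,205,246,246,148,166,117,123,77,99,178,178
H0004329,2018,M,X,Y,178,178,136,152,215,221,152,156,125,127,199,205,246,262,138,164,123,123,75,75,178,182
H0002251,2016,F,X,X,188,190,122,122,209,221,150,152,107,125,205,205,246,260,138,138,117,123,95,99,178,188
H0005831,2020,F,X,X,178,178,142,146,223,223,152,152,107,115,205,219,260,262,164,190,117,123,77,103,158,182
H0003936,2018,F,X,X,176,178,122,146,221,221,148,152,125,125,205,225,246,260,164,164,123,127,75,91,154,178
H0005362,2020,F,X,X,178,188,122,130,217,223,152,154,125,131,205,205,246,262,138,164,117,117,83,95,158,172
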