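# marker: rpoC1
# aligned_length: 452
taxon	Aphanizomenon flos-aquae	Aphanizomenon gracile	Dolichospermum planctonicum	Dolichospermum flos-aquae	Dolichospermum circinale	Cylindrospermopsis raciborskii	Chrysosporum ovalisporum	Sphaerospermopsis aphanizomenoides	Cuspidothrix issatschenkoi	Raphidiopsis mediterranea	Raphidiopsis curvata
Aphanizomenon flos-aquae
Aphanizomenon gracile	78.1
Dolichospermum planctonicum	77.2	81.2
Dolichospermum flos-aquae	75.4	74.6	72.9
Dolichospermum circinale	75.8	79.9	89.6	73.2
Cylindrospermopsis raciborskii	75.1	71.0	71.6	69.7	71.2
Chrysosporum ovalisporum	70.7	66.7	70.3	77.9	69.0	67.8
Sphaerospermopsis aphanizomenoides	93.5	77.7	75.9	74.6	76.4	76.1	70.7
Cuspidothrix issatschenkoi	79.8	79.5	76.3	74.8	78.4	73.5	71.9	80.5
Raphidiopsis mediterranea	73.4	70.4	71.7	69.5	69.6	96.4	66.0	74.5	72.8
Raphidiopsis curvata	76.5	73.2	74.4	70.8	72.0	94.2	69.6	77.1	72.5	93.7
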