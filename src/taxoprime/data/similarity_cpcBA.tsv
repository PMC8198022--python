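# marker: cpcBA
# aligned_length: 357
taxon	Aphanizomenon flos-aquae	Aphanizomenon gracile	Dolichospermum planctonicum	Dolichospermum flos-aquae	Cylindrospermopsis raciborskii	Chrysosporum ovalisporum	Sphaerospermopsis aphanizomenoides	Cuspidothrix issatschenkoi	Raphidiopsis mediterranea	Raphidiopsis curvata
Aphanizomenon flos-aquae
Aphanizomenon gracile	90.0
Dolichospermum planctonicum	81.2	77.9
Dolichospermum flos-aquae	90.0	100.0	77.9
Cylindrospermopsis raciborskii	67.8	64.3	66.9	64.3
Chrysosporum ovalisporum	66.4	63.5	66.4	63.5	68.3
Sphaerospermopsis aphanizomenoides	74.8	72.9	75.2	72.9	77.2	70.9
Cuspidothrix issatschenkoi	86.2	83.2	78.0	83.2	73.4	71.0	72.8
Raphidiopsis mediterranea	66.1	63.2	66.9	63.2	98.1	68.1	76.2	71.8
Raphidiopsis curvata	67.2	64.5	67.1	64.5	95.8	66.4	78.6	73.0	95.3
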