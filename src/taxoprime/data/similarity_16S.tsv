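# marker: 16S
# aligned_length: 1306
taxon	Aphanizomenon flos-aquae	Aphanizomenon gracile	Dolichospermum planctonicum	Dolichospermum flos-aquae	Dolichospermum circinale	Cylindrospermopsis raciborskii	Chrysosporum ovalisporum	Sphaerospermopsis reniformis	Sphaerospermopsis aphanizomenoides	Cuspidothrix issatschenkoi	Raphidiopsis mediterranea	Raphidiopsis curvata
Aphanizomenon flos-aquae
Aphanizomenon gracile	98.7
Dolichospermum planctonicum	98.1	98.2
Dolichospermum flos-aquae	97.8	98.4	97.3
Dolichospermum circinale	98.6	98.4	99.3	97.5
Cylindrospermopsis raciborskii	93.3	93.6	93.5	93.1	93.7
Chrysosporum ovalisporum	95.2	95.6	95.1	94.7	95.3	93.5
Sphaerospermopsis reniformis	93.1	93.3	93.1	92.0	92.9	96.1	93.8
Sphaerospermopsis aphanizomenoides	93.4	93.7	93.3	92.4	93.2	96.7	94.1	99.5
Cuspidothrix issatschenkoi	95.6	96.7	95.2	96.1	95.0	93.4	94.6	93.7	94.1
Raphidiopsis mediterranea	93.4	93.7	93.6	93.1	93.8	99.7	93.5	96.4	96.9	93.5
Raphidiopsis curvata	93.1	93.7	93.3	93.0	93.4	99.3	93.0	96.0	96.5	93.1	99.2
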