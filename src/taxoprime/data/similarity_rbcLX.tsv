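# marker: rbcLX
# aligned_length: 761
taxon	Aphanizomenon flos-aquae	Aphanizomenon gracile	Dolichospermum planctonicum	Dolichospermum flos-aquae	Dolichospermum circinale	Sphaerospermopsis aphanizomenoides	Sphaerospermopsis reniformis	Cuspidothrix issatschenkoi
Aphanizomenon flos-aquae
Aphanizomenon gracile	100.0
Dolichospermum planctonicum	94.9	94.9
Dolichospermum flos-aquae	89.0	89.0	90.9
Dolichospermum circinale	88.7	88.7	90.8	99.3
Sphaerospermopsis aphanizomenoides	85.4	85.4	85.0	82.1	81.6
Sphaerospermopsis reniformis	85.6	85.6	85.4	81.6	81.1	98.6
Cuspidothrix issatschenkoi	88.1	88.1	86.2	91.4	91.5	81.0	81.1
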