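# marker: rpoB
# aligned_length: 504
taxon	Aphanizomenon flos-aquae	Aphanizomenon gracile	Dolichospermum planctonicum	Dolichospermum circinale	Dolichospermum flos-aquae	Cuspidothrix issatschenkoi
Aphanizomenon flos-aquae
Aphanizomenon gracile	99.4
Dolichospermum planctonicum	80.5	79.9
Dolichospermum circinale	74.8	74.8	85.8
Dolichospermum flos-aquae	74.6	74.6	69.3	64.7
Cuspidothrix issatschenkoi	84.5	84.2	77.5	69.6	75.1
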