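key	display_name	min_identity	min_coverage	expects_recoding	recoded_index	query_only
pylB	3-methylornithine synthase	35.0	70.0	-	-1	0
pylC	3-methylornithine--L-lysine ligase	35.0	70.0	-	-1	0
pylD	3-methylornithyl-N6-L-lysine dehydrogenase	35.0	70.0	-	-1	0
pylS_N	pyrrolysyl-tRNA synthetase N-terminal domain	35.0	70.0	-	-1	0
pylS_C	pyrrolysyl-tRNA synthetase C-terminal domain	35.0	70.0	-	-1	0
mttB	trimethylamine methyltransferase (Pyl-containing)	35.0	70.0	TAG>O	230	0
ramA	methylamine methyltransferase corrinoid protein reductive activase	35.0	70.0	-	-1	0
mttC	trimethylamine methyltransferase cognate corrinoid protein	35.0	70.0	-	-1	0
cutC	choline trimethylamine-lyase	35.0	70.0	-	-1	0
cutD	choline trimethylamine-lyase activating enzyme	35.0	70.0	-	-1	0
grdA_like	glycine betaine reductase selenoprotein A homolog	35.0	70.0	TGA>U	150	0
selA	L-seryl-tRNA(Sec) selenium transferase	35.0	70.0	-	-1	0
selB	selenocysteine-specific translation elongation factor	35.0	70.0	-	-1	0
selD	selenide, water dikinase	35.0	70.0	-	-1	0
bcct	betaine/carnitine/choline transporter family protein	35.0	70.0	-	-1	0
mtbB	dimethylamine methyltransferase	35.0	70.0	TAG>O	220	1
mtmB_like	monomethylamine methyltransferase homolog	35.0	70.0	TAG>O	215	1
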