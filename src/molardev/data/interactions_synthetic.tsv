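# Synthetic pathway-interaction table (format demonstration only).
# One row per published perturbation-response observation: gene, pathway,
# tissue (epithelium/mesenchyme), perturbation (mapped to activation or
# inhibition of the pathway), response of the gene (+ up, - down, o none)
# and the source label. Gene names are real tooth-development genes but the
# rows are invented to exercise every classification rule; supply your own
# curated table for real analyses.
gene	pathway	tissue	perturbation	response	source
Msx1	BMP4	mesenchyme	bmp4_treatment	+	primary_screen
Msx1	BMP4	mesenchyme	bmp4_knockout	-	primary_screen
Id1	BMP4	epithelium	bmp4_treatment	+	primary_screen
Sostdc1	BMP4	epithelium	bmp4_treatment	+	literature_a
Bmper	BMP4	mesenchyme	bmp4_treatment	-	primary_screen
Shh	BMP4	epithelium	bmp4_knockout	+	primary_screen
Dlx1	BMP4	epithelium	bmp4_treatment	+	primary_screen
Dlx1	BMP4	mesenchyme	bmp4_treatment	-	primary_screen
Egr1	BMP4	mesenchyme	bmp4_treatment	+	primary_screen
Egr1	BMP4	mesenchyme	bmp4_treatment	-	literature_b
Nt5e	BMP4	mesenchyme	bmp4_treatment	o	primary_screen
Axin2	Wnt	epithelium	gsk3b_inhibition	+	primary_screen
Axin2	Wnt	mesenchyme	ctnnb1_knockout	-	primary_screen
Kremen1	Wnt	epithelium	ctnnb1_overexpression	+	primary_screen
Dkk1	Wnt	epithelium	wnt_treatment	+	primary_screen
Sfrp2	Wnt	mesenchyme	dkk1_overexpression	+	primary_screen
Wif1	Wnt	epithelium	lef1_knockout	-	primary_screen
Ptch1	Wnt	epithelium	wnt_treatment	-	literature_a
Ptch1	Wnt	epithelium	wnt_treatment	+	primary_screen
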