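dataset	switch_type	lca_state	lca_class	count
Eubacteria	AU<->GC	AU	terminal	6
Eubacteria	AU<->GC	GC	terminal	32
Eubacteria	AU<->GC	GU	intermediate	13
Eubacteria	AU<->GC	AC	intermediate	0
Eubacteria	AU<->GC	-	multiple	2
Eubacteria	AU<->CG	AU	terminal	5
Eubacteria	AU<->CG	CG	terminal	0
Eubacteria	AU<->CG	AG	intermediate	0
Eubacteria	AU<->CG	UC	intermediate	2
Eubacteria	AU<->CG	-	multiple	0
Eubacteria	AU<->UA	AU	terminal	0
Eubacteria	AU<->UA	UA	terminal	0
Eubacteria	AU<->UA	UU	intermediate	0
Eubacteria	AU<->UA	AA	intermediate	0
Eubacteria	AU<->UA	-	multiple	1
Eubacteria	GC<->CG	CG	terminal	0
Eubacteria	GC<->CG	GC	terminal	0
Eubacteria	GC<->CG	CC	intermediate	0
Eubacteria	GC<->CG	GG	intermediate	0
Eubacteria	GC<->CG	-	multiple	1
Fungi	AU<->GC	AU	terminal	27
Fungi	AU<->GC	GC	terminal	33
Fungi	AU<->GC	GU	intermediate	5
Fungi	AU<->GC	AC	intermediate	5
Fungi	AU<->GC	-	multiple	1
Fungi	AU<->CG	AU	terminal	4
Fungi	AU<->CG	CG	terminal	6
Fungi	AU<->CG	AG	intermediate	0
Fungi	AU<->CG	UC	intermediate	0
Fungi	AU<->CG	-	multiple	2
Fungi	AU<->UA	AU	terminal	8
Fungi	AU<->UA	UA	terminal	4
Fungi	AU<->UA	UU	intermediate	0
Fungi	AU<->UA	AA	intermediate	0
Fungi	AU<->UA	-	multiple	2
Fungi	GC<->CG	CG	terminal	12
Fungi	GC<->CG	GC	terminal	9
Fungi	GC<->CG	CC	intermediate	1
Fungi	GC<->CG	GG	intermediate	4
Fungi	GC<->CG	-	multiple	0
Plants	AU<->GC	AU	terminal	7
Plants	AU<->GC	GC	terminal	31
Plants	AU<->GC	GU	intermediate	5
Plants	AU<->GC	AC	intermediate	0
Plants	AU<->GC	-	multiple	0
Plants	AU<->CG	AU	terminal	2
Plants	AU<->CG	CG	terminal	0
Plants	AU<->CG	AG	intermediate	0
Plants	AU<->CG	UC	intermediate	0
Plants	AU<->CG	-	multiple	1
Plants	AU<->UA	AU	terminal	0
Plants	AU<->UA	UA	terminal	0
Plants	AU<->UA	UU	intermediate	0
Plants	AU<->UA	AA	intermediate	0
Plants	AU<->UA	-	multiple	0
Plants	GC<->CG	CG	terminal	4
Plants	GC<->CG	GC	terminal	10
Plants	GC<->CG	CC	intermediate	0
Plants	GC<->CG	GG	intermediate	1
Plants	GC<->CG	-	multiple	0
Animals	AU<->GC	AU	terminal	6
Animals	AU<->GC	GC	terminal	21
Animals	AU<->GC	GU	intermediate	8
Animals	AU<->GC	AC	intermediate	0
Animals	AU<->GC	-	multiple	2
Animals	AU<->CG	AU	terminal	4
Animals	AU<->CG	CG	terminal	3
Animals	AU<->CG	AG	intermediate	0
Animals	AU<->CG	UC	intermediate	0
Animals	AU<->CG	-	multiple	0
Animals	AU<->UA	AU	terminal	7
Animals	AU<->UA	UA	terminal	1
Animals	AU<->UA	UU	intermediate	0
Animals	AU<->UA	AA	intermediate	0
Animals	AU<->UA	-	multiple	0
Animals	GC<->CG	CG	terminal	6
Animals	GC<->CG	GC	terminal	7
Animals	GC<->CG	CC	intermediate	0
Animals	GC<->CG	GG	intermediate	0
Animals	GC<->CG	-	multiple	0
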