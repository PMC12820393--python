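substrate_id	sequence	protease_class	subclass	ph_opt_low	ph_opt_high	custom	derivation	aliases
Ac-DGPYSLVA-AMC	DGPYSLVA	serine	elastase-like	7.5	8.5	yes	CNTN1 791-799
Ac-GDGPYSLVA-AMC	GDGPYSLVA	serine	elastase-like	7.5	8.5	yes	CNTN1 790-799
Ac-PHLVRQKR-AMC	PHLVRQKR	serine	furin-like	6.5	8.0	yes	DSG2 42-49
Ac-KHPHLVRQKR-AMC	KHPHLVRQKR	serine	furin-like	6.5	8.0	yes	DSG2 40-49	Ac-KHPHLVRQR-AMC
Pyr-RTKR-AMC	RTKR	serine	furin-like	6.5	8.0	no		RTKR-AMC
Ac-RRPL-AMC	RRPL	serine	SKI-1/S1P-like	7.5	8.0	yes	multiple proteins
Ac-VFRSLK-AMC	VFRSLK	serine	SKI-1/S1P-like	7.5	8.0	yes	PLRG1 14-19; SKI-1/S1P 142-147
Ac-ANQRRHLL-AMC	ANQRRHLL	serine	SKI-1/S1P-like	7.5	8.0	yes	ATF6 412-419
Ac-ERSLK-AMC	ERSLK	serine	SKI-1/S1P-like	7.5	8.0	yes	GIIb 381-385; MGAM 1409-1413
R-AMC	R	serine	trypsin-like			no		Ac-R-AMC
Ac-RRHL-AMC	RRHL	cysteine	cathepsin-like	5.0	7.0	yes	multiple proteins
Ac-RRLQ-AMC	RRLQ	cysteine	cathepsin-like	5.0	7.0	yes	multiple proteins
Ac-RSVL-AMC	RSVL	cysteine	cathepsin-like	5.0	7.0	yes	multiple proteins
Ac-PANQRRHL-AMC	PANQRRHL	cysteine	cathepsin-like	5.0	7.0	yes	ATF6 411-418
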