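gene_id	function	location
AO090026000001	PKS	SB
AO090206000074	PKS	SB
AO090701000530	PKS	SB
AO090003001097	NRPS	SB
AO090103000167	NRPS	SB
AO090005001026	NRPS	SB
AO090001000516	NRPS	SB
AO090003000945	NRPS	SB
AO090102000545	PKS	NSB
AO090113000209	PKS	NSB
AO090010000048	PKS	NSB
AO090005000961	PKS	NSB
AO090010000404	PKS	NSB
AO090701000826	PKS	NSB
AO090009000131	PKS	NSB
AO090103000223	NRPS	NSB
AO090026000585	NRPS	NSB
AO090026000378	NRPS	NSB
AO090102000338	NRPS	NSB
AO090010000498	NRPS	NSB
AO090020000240	NRPS	NSB
AO090003001545	NRPS	NSB
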