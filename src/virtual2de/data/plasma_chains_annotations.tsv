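# mature-chain annotations for the packaged plasma proteins, v1
# residue coordinates are 1-based inclusive in the precursor
accession	chain_name	start	end
P02768	mature	25	609
P00738	mature	19	406
P00738	alpha2	19	160
P00738	beta	162	406
P69905	mature	2	142
P68871	mature	2	147
P02766	mature	21	147
P02652	mature	24	100
P02763	mature	19	201
P02741	mature	19	224
P02741	mature_1_205	19	223
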