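# Built-in disubstituted scaffold registry: id <TAB> pattern <TAB> description
# Patterns are SMARTS with ring bonds written as "~" (any order) so they match
# aromatic, Kekulé and perceived single-bond connection tables alike.  The two
# attachment positions carry atom maps :1 and :2; substituent atoms are found
# as non-scaffold neighbours at match time.
ortho_benzene	[#6:1]1~[#6:2]~[#6]~[#6]~[#6]~[#6]~1	benzene ring substituted on two adjacent carbons (1,2 pattern)
bcp_12	[#6:1]12~[#6:2]~[#6](~[#6]~1)~[#6]~2	bicyclo[1.1.1]pentane substituted at a bridgehead and an adjacent bridge carbon
bch_12	[#6:1]12~[#6:2]~[#6]~[#6](~[#6]~1)~[#6]~2	bicyclo[2.1.1]hexane substituted at a bridgehead and the adjacent two-carbon-bridge position
oxa_bch	[#6:1]12~[#8]~[#6]~[#6](~[#6:2]~1)~[#6]~2	2-oxabicyclo[2.1.1]hexane substituted at the oxygen-bearing bridgehead and an adjacent one-carbon bridge
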