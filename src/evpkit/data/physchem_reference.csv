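# Literature-reported physicochemical measurements for four marketed
# ortho-substituted-phenyl bioactives and their saturated analogues:
# the carbocyclic bicyclo[2.1.1]hexane replacement and the
# 2-oxabicyclo[2.1.1]hexane replacement.
# solubility: kinetic solubility in PBS pH 7.4, uM
# clogp: calculated octanol-water partition coefficient
# logd: measured octanol-buffer distribution coefficient at pH 7.4;
#       empty when outside the reliable 1.0-4.5 assay window
# clint: intrinsic clearance in human liver microsomes, ul/min/mg
# provenance: "reported" = numeric value stated in the source text;
#             "estimated" = synthetic placeholder consistent with the
#             qualitative trends stated in the source (flagged so that
#             no quantitative claim rests on it)
compound,parent,role,solubility_um,clogp,logd,clint,provenance
fluxapyroxad,fluxapyroxad,parent,25,3.1,3.5,28,"solubility/logd/clint reported; clogp estimated"
28,fluxapyroxad,carbocycle,34,3.6,4.3,35,"solubility/logd/clint reported; clogp estimated"
29,fluxapyroxad,oxa,155,2.1,2.8,23,"solubility/logd/clint reported; clogp estimated"
boscalid,boscalid,parent,11,2.9,3.6,26,"solubility/logd/clint reported; clogp estimated"
30,boscalid,carbocycle,17,3.4,3.5,12,"solubility/logd/clint reported; clogp estimated"
31,boscalid,oxa,152,1.9,2.7,3,"solubility/logd/clint reported; clogp estimated"
phthalylsulfathiazole,phthalylsulfathiazole,parent,170,0.9,,0,"solubility reported; clogp/clint estimated; logd outside reliable window"
32,phthalylsulfathiazole,carbocycle,101,0.9,,0,"solubility reported; clogp/clint estimated; logd outside reliable window"
33,phthalylsulfathiazole,oxa,158,-0.1,,0,"solubility reported; clogp/clint estimated; logd outside reliable window"
lomitapide,lomitapide,parent,1,8.7,,55,"clint reported; solubility/clogp estimated (poorly soluble); logd outside reliable window"
34,lomitapide,carbocycle,1,8.7,,157,"clint reported; solubility/clogp estimated (poorly soluble); logd outside reliable window"
35,lomitapide,oxa,1,7.7,,87,"clint reported; solubility/clogp estimated (poorly soluble); logd outside reliable window"
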