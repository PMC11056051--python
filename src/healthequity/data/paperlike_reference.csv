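quantity,resource,category,year,value,rounding
growth,beds,Yi,,140,percent_int
growth,beds,OMC,,127,percent_int
growth,beds,NMC,,121,percent_int
growth,doctors,Yi,,20,percent_int
growth,doctors,Zang,,11,percent_int
growth,doctors,NMC,,61,percent_int
growth,nurses,Yi,,240,percent_int
growth,nurses,OMC,,316,percent_int
growth,nurses,NMC,,198,percent_int
negative_share,doctors,Yi,,33,percent_int
negative_share,doctors,Zang,,50,percent_int
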