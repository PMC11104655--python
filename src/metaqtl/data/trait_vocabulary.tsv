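raw_name	trait_class
grain area	GMT
grain diameter	GMT
grain length	GMT
grain perimeter	GMT
grain thickness	GMT
grain volume	GMT
grain width	GMT
grain morphology	GMT
grain density	GN
grain number	GN
grain number per plant	GN
grain number per spike	GN
grain number per square meter	GN
grains per spike	GN
fertile spike number	SRT
number of spike	SRT
number of spikes	SRT
number of spikelets	SRT
number of spikes per plant	SRT
number of spikes per square meter	SRT
spikes per plant	SRT
spikes per square meter	SRT
spikes per line	SRT
spike density	SRT
spike length	SRT
spike number	SRT
spikelet number per spike	SRT
grain weight per square meter	GW
grain weight per plant	GW
grain weight per spike	GW
thousand grain weight	GW
grain weight	GW
grain yield	GY
grain yield per plant	GY
yield	GY
grain filling period	GFRT
grain filling rate	GFRT
days to maturity	GPT
flowering date	GPT
heading date	GPT
maturity date	GPT
biomass	BY
biomass yield	BY
plant height	PH
tiller number	TN
number of tillers	TN
tillers per plant	TN
harvest index	HI
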