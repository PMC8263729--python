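threat,d_rmax_km,weight,decay
cropland,5,0.5,exponential
city_town,9,1.0,exponential
rural_settlements,6,0.6,exponential
other_construction,2,1.0,exponential
unused_land,1,0.4,linear
land_reclamation,2,0.3,linear
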