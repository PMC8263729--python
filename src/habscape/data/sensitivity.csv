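habitat,H,cropland,city_town,rural_settlements,other_construction,unused_land,land_reclamation
cropland,0.4,0.0,0.8,0.6,0.7,0.4,0.4
forestland,1.0,0.7,0.9,0.8,0.8,0.5,0.5
bush_forest,1.0,0.6,0.8,0.6,0.7,0.4,0.4
sparse_woodland,0.8,0.7,0.8,0.7,0.8,0.5,0.5
other_woodland,0.6,0.7,0.8,0.7,0.8,0.4,0.4
high_cover_grassland,0.9,0.6,0.7,0.7,0.7,0.7,0.7
medium_cover_grassland,0.8,0.6,0.7,0.7,0.7,0.7,0.7
low_cover_grassland,0.6,0.6,0.7,0.7,0.7,0.7,0.7
water,0.8,0.4,0.7,0.6,0.7,0.4,0.4
unused_land,0.4,0.3,0.5,0.4,0.5,0.0,0.0
land_reclamation,0.0,0.0,0.0,0.0,0.0,0.0,0.0
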