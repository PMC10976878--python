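category,fire_type,species,ef_g_per_kg
forest,rx,PM2.5,17.57
forest,wildfire,PM2.5,23.2
shrubland,any,PM2.5,7.06
grassland,any,PM2.5,8.51
woody_rsc,any,PM2.5,33
duff_rsc,any,PM2.5,35.3
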