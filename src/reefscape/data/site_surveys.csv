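site,island,landside_environment,max_depth_m,surface_m2,dominant_substrate,substrate_pct,seagrass_cov_pct,seagrass_sd_pct,macroalgae_cov_pct,macroalgae_sd_pct,fish_per_10m,turtle_density_per_1e4m2
Nasau,Makogai,sandy beach,3,28800,sand,78,3.4,4.3,46.7,35.9,15.8,9.8
Sawesi,Makogai,sandy beach,5,28000,mixed,39,1.2,1.2,39.3,28.7,2.0,3.2
Takewa,Makogai,sandy beach,4,14600,rock,45,,,7.7,19.1,6.1,1.0
Vagabia,Makogai,mangrove vegetation,3,64600,sand,83,9.4,13.8,10.3,19.8,7.4,4.8
Matauvia,Yadua,sandy beach,6,45400,sand,100,38.7,20.6,0.7,3.7,6.1,1.4
Navolawara,Yadua,sandy beach,8,30900,mixed,26,,,12.7,19.4,12.7,1.0
Talai,Yadua,sandy beach,4,47500,sand,55,34.1,40.8,21.4,25.7,4.9,2.0
Votua,Yadua,mangrove vegetation,7,68300,sand,71,31.5,4.4,15.1,15.5,5.7,2.0
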