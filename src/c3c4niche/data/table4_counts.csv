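variable,comparison,k,n,printed_p,printed_significant
climate_PC1,C3C4_vs_C3_all,14,19,0.019,0
climate_PC1,C3C4_vs_C3_withC4,12,14,0.0018,1
climate_PC1,C4_vs_C3C4,8,15,0.61,0
soil_PC1,C3C4_vs_C3_all,10,19,0.65,0
soil_PC1,C3C4_vs_C3_withC4,8,14,0.42,0
soil_PC1,C4_vs_C3C4,6,15,0.61,0
growing_season_temperature,C3C4_vs_C3_all,14,19,0.019,0
growing_season_temperature,C3C4_vs_C3_withC4,13,14,0.00012,1
growing_season_temperature,C4_vs_C3C4,5,15,0.30,0
minimum_temperature,C3C4_vs_C3_all,13,19,0.064,0
minimum_temperature,C3C4_vs_C3_withC4,12,14,0.0018,1
minimum_temperature,C4_vs_C3C4,8,15,0.61,0
minimum_precipitation,C3C4_vs_C3_all,7,19,0.36,0
minimum_precipitation,C3C4_vs_C3_withC4,3,14,0.057,0
minimum_precipitation,C4_vs_C3C4,7,15,1,0
rainfall_seasonality,C3C4_vs_C3_all,14,19,0.019,0
rainfall_seasonality,C3C4_vs_C3_withC4,12,14,0.0018,1
rainfall_seasonality,C4_vs_C3C4,6,15,0.61,0
organic_carbon,C3C4_vs_C3_all,11,19,0.36,0
organic_carbon,C3C4_vs_C3_withC4,6,14,0.79,0
organic_carbon,C4_vs_C3C4,5,15,0.30,0
TEB,C3C4_vs_C3_all,8,19,0.65,0
TEB,C3C4_vs_C3_withC4,5,14,0.42,0
TEB,C4_vs_C3C4,6,15,0.61,0
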