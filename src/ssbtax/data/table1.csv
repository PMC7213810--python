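parameter,value,ci_low,ci_high,units
mean_bmi,23.38,,,kg/m^2
weekly_ssb_servings_per_capita,1.55,,,300 mL servings/week
ssb_price,3.77,,,ZMW per 300 mL serving
fruit_juice_price,4.93,,,ZMW per 300 mL serving
milk_price,3.64,,,ZMW per 300 mL serving
own_price_elasticity_ssb,-1.30,-1.51,-1.10,dimensionless
cross_price_elasticity_fruit_juice,0.32,0.01,0.77,dimensionless
cross_price_elasticity_milk,0.18,-0.10,0.34,dimensionless
pass_on_rate,1.00,0.80,1.20,fraction
fx_rate,9.53,,,ZMW per USD
consumer_share,0.13,,,fraction of population
adult_population,8344486,,,persons aged 15+
female_population,4271631,,,persons
male_population,4072855,,,persons
total_population,15473905,,,persons
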