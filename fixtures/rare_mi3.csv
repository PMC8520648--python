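arm,age,sex,diabetes,event,fatal,severity_attr,time,observed
treatment,68.04717079754431,1,0,0,0,,1825.0,0
treatment,54.60015893759504,0,0,0,0,,1825.0,0
treatment,72.50451195806457,0,0,0,0,,1825.0,0
treatment,74.40564716391214,1,1,0,0,,1825.0,0
treatment,45.48964811346164,0,1,0,0,,1825.0,0
treatment,51.97820493137682,0,1,0,0,,1825.0,0
treatment,66.27840403167285,1,0,0,0,,1825.0,0
treatment,61.83757407656418,1,0,0,0,,1825.0,0
treatment,64.83198842495712,0,1,0,0,,1825.0,0
treatment,56.4695607242642,1,0,0,0,,1825.0,0
treatment,73.79397974862829,1,1,0,0,,1825.0,0
treatment,72.77791935428948,1,0,0,0,,1825.0,0
treatment,65.66030697561216,0,0,0,0,,1825.0,0
treatment,76.27241206968033,0,0,0,0,,1825.0,0
treatment,69.67509342252046,0,0,0,0,,1825.0,0
treatment,56.40707537116762,0,0,0,0,,1825.0,0
treatment,68.68750784082499,0,0,0,0,,1825.0,0
treatment,55.411173991710015,0,1,0,0,,1825.0,0
treatment,73.78450301307272,1,1,0,0,,1825.0,0
treatment,64.50074089013746,1,0,0,0,,1825.0,0
treatment,63.151376364547396,0,0,0,0,,1825.0,0
treatment,58.190704555960586,0,0,0,0,,1825.0,0
treatment,77.2254133867403,0,0,0,0,,1825.0,0
treatment,63.45470517931198,0,0,0,0,,1825.0,0
treatment,60.71672177836893,0,0,0,0,,1825.0,0
treatment,61.478664495117705,0,0,0,0,,1825.0,0
treatment,70.32309185553349,0,0,0,0,,1825.0,0
treatment,68.65444064364078,1,0,0,0,,1825.0,0
treatment,69.12732611595989,1,1,0,0,,1825.0,0
treatment,69.30821003007883,1,0,0,0,,1825.0,0
treatment,86.41647600870462,1,0,0,0,,1825.0,0
treatment,60.93584983615384,1,0,0,0,,1825.0,0
treatment,59.87757270928463,0,0,0,0,,1825.0,0
treatment,56.86227271752122,1,0,0,0,,1825.0,0
treatment,71.15979422575495,1,1,0,0,,1825.0,0
treatment,76.28972292720891,1,0,0,0,,1825.0,0
treatment,63.86052542345125,1,0,0,0,,1825.0,0
treatment,56.59843523037472,0,0,0,0,,1825.0,0
treatment,56.755187843087604,0,0,0,0,,1825.0,0
treatment,71.50592787824701,0,0,0,0,,1825.0,0
control,74.82739511023058,0,0,0,0,,1825.0,0
control,60.00704401460848,0,0,0,0,,1825.0,0
control,53.150562335829754,1,0,0,0,,1825.0,0
control,55.34883237767628,1,0,0,0,,1825.0,0
control,57.74773935464247,1,0,0,0,,1825.0,0
control,86.28469732435164,1,0,0,0,,1825.0,0
control,56.78613320775614,0,0,0,0,,1825.0,0
control,73.38489203736344,1,0,0,0,,1825.0,0
control,55.97072821912974,0,0,0,0,,1825.0,0
control,74.31573012874244,0,0,0,0,,1825.0,0
control,68.84950966105863,0,0,0,0,,1825.0,0
control,63.43362102341909,1,0,0,0,,1825.0,0
control,64.59237473864566,0,0,0,0,,1825.0,0
control,58.452123045706095,0,0,0,0,,1825.0,0
control,69.4607220148208,0,0,0,0,,1825.0,0
control,60.4501651965922,1,0,0,0,,1825.0,0
control,52.743942362327516,1,1,0,0,,1825.0,0
control,52.22062425680381,0,1,0,0,,1825.0,0
control,66.72587917722119,1,0,0,0,,1825.0,0
control,80.79091256410435,1,1,0,0,,1825.0,0
control,66.59991613573439,0,0,0,0,,1825.0,0
control,63.813616738901175,0,0,0,0,,1825.0,0
control,67.85826139602543,0,1,0,0,,1825.0,0
control,78.06001741706825,1,0,0,0,,1825.0,0
control,67.19382501363856,0,1,0,0,,1825.0,0
control,60.890727691662626,1,0,0,0,,1825.0,0
control,76.06288710059889,0,1,0,0,,1825.0,0
control,69.28756438461613,0,1,0,0,,1825.0,0
control,80.35755991995993,1,1,0,0,,1825.0,0
control,66.83234437221905,1,1,0,0,,1825.0,0
control,52.755309682795,1,1,0,0,,1825.0,0
control,51.318408007543354,0,1,0,0,,1825.0,0
control,81.5092793223125,0,0,0,0,,1825.0,0
control,82.23665720783296,0,0,0,0,,1825.0,0
control,63.20480786717399,0,0,0,0,,1825.0,0
control,61.16812678864012,0,0,0,0,,1825.0,0
control,79.61444292242203,0,0,0,0,,1825.0,0
control,53.92954317956512,1,0,0,0,,1825.0,0
control,56.05272981044173,1,0,0,0,,1825.0,0
control,71.43326794689044,0,1,0,0,,1825.0,0
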