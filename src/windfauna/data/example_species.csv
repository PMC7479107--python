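name,size_class,months_present,periods,flight_height_min_m,flight_height_max_m,flight_type,flock_class,collision_record,strategy,redbook,socioeconomic
Falco naumanni,small,6,breeding,50,90,indirect,2-5,scarce,K,V,1
Gyps fulvus,large,12,breeding;winter,100,600,indirect,6-10,usual,K,LC,0
Turdus merula,small,12,breeding;winter,0,10,direct,1,none,R,LC,0
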