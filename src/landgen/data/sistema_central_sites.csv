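name,population,mountain_range,env_class,elevation,tmax,tmin,lat,lon
Najarra baja,NAJ,GDM,Marginal,1850,"26,5",-5.9,"40°49′23,46″N",3°49′52.53″W
Morrena Peñalara,MOR,GDM,Marginal,1980,24.7,-5.7,40°50′11.82″N,3°57′0.91″W
Pico de Peñalara,PEN,GDM,Optimal,2400,24.1,-7.8,40°51′2.11″N,3°57′24.02″W
El Sestil,SES,GRD,Marginal,1900,28,-5.9,40°16′24.45″N,5°14′54.93″W
Los Campanarios,CAM,GRD,Marginal,2000,27.7,-6,40°15′42.63″N,5°12′55.74″W
Altos del Morezón,ZON,GRD,Optimal,2380,26.9,-7.7,40°14′57.5″N,5°16′8.3″W
Las Cimeras,RUI,BJR,Marginal,2000,26.7,-6.7,40°21′7.03″N,5°40′59.71″W
Pico El Aguila,AGI,BJR,Marginal,1950,26.9,-6.1,40°21′12.36″N,5°41′46.52″W
Canchal Negro,NEG,BJR,Optimal,2360,26,-7.2,40°20′19.97″N,5°41′22.27″W
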