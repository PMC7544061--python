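species_name,common_name,canopy_spread_ft,height_ft,light_requirement,breakage_resistant,site_type,allergenicity,growth_rate,transpiration_rate,leaf_area
Acer campestre,hedge maple,30,35,full_sun,true,street;park_yard,medium,slow,1.1,0.9
Acer rubrum,red maple,40,60,partial,false,street;park_yard,high,fast,1.4,1.3
Acer saccharum,sugar maple,45,70,shade_tolerant,true,park_yard,medium,medium,1.3,1.5
Amelanchier laevis,Allegheny serviceberry,20,25,partial,true,street;park_yard,low,medium,0.7,0.5
Betula nigra,river birch,45,60,full_sun,false,park_yard,high,fast,1.6,1.1
Carpinus betulus,European hornbeam,30,45,partial,true,street;park_yard,medium,slow,1.0,1.0
Carpinus caroliniana,American hornbeam,25,30,shade_tolerant,true,park_yard,medium,slow,0.9,0.8
Celtis occidentalis,common hackberry,45,55,full_sun,true,street;park_yard,low,medium,1.2,1.2
Cercidiphyllum japonicum,katsura tree,35,45,partial,true,park_yard,low,medium,1.1,1.1
Cladrastis kentukea,American yellowwood,40,40,full_sun,false,park_yard,low,medium,1.0,1.0
Cornus mas,cornelian cherry dogwood,18,22,partial,true,street;park_yard,low,slow,0.6,0.4
Crataegus crus-galli,cockspur hawthorn,25,28,full_sun,true,street,low,slow,0.7,0.5
Eucommia ulmoides,hardy rubber tree,35,50,full_sun,true,street,low,medium,1.1,1.0
Fagus grandifolia,American beech,50,70,shade_tolerant,true,park_yard,medium,slow,1.3,1.6
Ginkgo biloba,ginkgo,35,60,full_sun,true,street;park_yard,low,slow,0.8,0.9
Gleditsia triacanthos,honeylocust,40,55,full_sun,true,street;park_yard,low,fast,1.2,0.8
Gymnocladus dioicus,Kentucky coffeetree,45,65,full_sun,true,street;park_yard,low,slow,1.1,1.2
Koelreuteria paniculata,goldenrain tree,30,35,full_sun,false,street,low,medium,0.9,0.8
Liquidambar styraciflua,sweetgum,45,70,full_sun,false,park_yard,medium,medium,1.5,1.4
Liriodendron tulipifera,tulip tree,40,80,full_sun,false,park_yard,low,fast,1.7,1.5
Maackia amurensis,Amur maackia,25,28,full_sun,true,street,low,slow,0.7,0.5
Malus baccata,Siberian crabapple,22,25,full_sun,false,street;park_yard,low,medium,0.7,0.5
Metasequoia glyptostroboides,dawn redwood,30,80,full_sun,true,park_yard,low,fast,1.6,1.3
Nyssa sylvatica,black tupelo,30,50,partial,true,street;park_yard,low,slow,1.2,1.1
Ostrya virginiana,American hophornbeam,28,35,shade_tolerant,true,street;park_yard,medium,slow,0.9,0.8
Platanus x acerifolia,London planetree,55,75,full_sun,true,street;park_yard,high,fast,1.8,1.7
Quercus bicolor,swamp white oak,50,60,full_sun,true,street;park_yard,high,medium,1.5,1.6
Quercus coccinea,scarlet oak,45,65,full_sun,true,park_yard,high,medium,1.4,1.5
Quercus palustris,pin oak,40,65,full_sun,true,street;park_yard,high,fast,1.5,1.4
Quercus rubra,northern red oak,50,70,full_sun,true,street;park_yard,high,fast,1.6,1.7
Styphnolobium japonicum,Japanese pagoda tree,40,55,full_sun,false,street,low,medium,1.1,1.0
Syringa reticulata,Japanese tree lilac,20,25,full_sun,true,street,low,medium,0.6,0.4
Tilia cordata,littleleaf linden,35,55,partial,true,street;park_yard,medium,medium,1.3,1.2
Zelkova serrata,Japanese zelkova,45,60,full_sun,true,street;park_yard,low,fast,1.4,1.3
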