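crop_code,crop_class,gmin,gmax,ktmp,tmin,topmin,topmax,tmax,rmin,ropmin,ropmax,rmax,phmin,phopmin,phopmax,phmax,has_mapspam
maize,Cereals,90,140,0,10,18,33,47,400,600,1200,1800,4.5,5.5,7.0,8.5,true
pmillet,Cereals,60,120,0,12,25,35,45,200,400,900,1700,4.5,5.5,7.0,8.3,true
fmillet,Cereals,90,150,0,11,22,32,42,300,500,1000,1700,4.5,5.5,7.5,8.3,true
sorghum,Cereals,90,140,0,8,24,35,40,300,500,1000,2000,4.3,5.5,7.5,8.5,true
rice,Cereals,90,150,5,10,20,30,36,600,1000,2000,4000,4.0,5.5,7.0,8.0,true
wheat,Cereals,90,130,-4,5,15,23,27,300,500,900,1600,5.0,6.0,7.5,8.5,true
teff,Cereals,60,120,2,8,15,25,35,300,450,900,1300,4.8,6.0,7.5,8.2,false
fonio,Cereals,70,130,4,15,22,28,35,400,700,1200,2000,4.5,5.5,7.0,7.8,false
cowpea,Pulses,65,120,0,12,20,32,40,300,500,1100,1900,4.5,5.5,7.5,8.5,true
soybean,Pulses,75,140,0,10,20,33,38,400,600,1300,1800,4.5,5.5,7.0,8.4,true
bambnut,Pulses,90,150,3,14,20,28,38,500,750,1400,2400,4.3,5.0,6.5,7.0,false
peanut,Pulses,90,140,0,10,22,28,45,400,600,1300,2000,4.3,5.5,7.0,8.7,true
commbean,Pulses,65,120,0,7,16,24,32,300,500,1500,2600,4.5,5.5,7.5,8.6,true
chickpea,Pulses,90,180,-6,7,15,29,35,300,400,700,1800,5.0,6.0,8.0,9.0,true
cassava,Roots,180,365,0,10,20,29,35,500,800,2000,5000,4.0,5.5,7.0,9.0,true
tannia,Roots,240,365,5,12,20,30,36,900,1400,2500,4500,4.5,5.5,6.5,7.5,false
potato,Roots,90,150,-2,7,15,25,30,300,500,800,2000,4.2,5.0,6.5,8.5,true
cocoyam,Roots,180,300,5,12,21,30,35,1000,1500,2500,4000,4.2,5.5,7.0,8.0,true
sweetpotato,Roots,100,170,2,10,20,30,35,500,750,1500,3000,4.5,5.5,7.0,8.5,true
whiteyam,Roots,180,300,8,15,22,31,38,900,1200,2500,4000,4.5,5.5,7.0,8.0,true
banana,Banana,300,365,6,14,22,32,38,900,1300,2600,5000,4.5,5.5,7.5,8.5,true
enset,Banana,300,365,4,10,16,24,30,900,1100,1800,2800,5.2,6.0,7.5,8.0,false
plantain,Banana,300,365,6,14,22,30,36,1000,1400,2600,5000,4.5,5.5,7.0,8.0,true
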