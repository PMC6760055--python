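symbol,process,name,units,low,mid,high
X1,Ethanol extraction,Ethanol solution concentration for extraction,v/v %,80,85,90
X2,Ethanol extraction,Extraction time,h,6.0,8.0,10.0
X3,Ethanol extraction,Ethanol solution volume,mL,600,800,1000
X4,Concentration,Volume of concentrated extract,mL,100,150,200
X5,Water precipitation,Water added for water precipitation,mL,300,400,500
X6,Column chromatography,Sampling flow rate,BV/h,1.0,1.5,2.0
X7,Column chromatography,Washing flow rate,BV/h,1.0,1.5,2.0
X8,Column chromatography,Water volume,BV,1.0,2.0,3.0
X9,Column chromatography,Ethanol solution concentration for elution,v/v %,55,60,65
X10,Column chromatography,Elution time,min,120,150,180
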