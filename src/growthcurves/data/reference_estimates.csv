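dataset,model,parameter,value
1,monomolecular,a,104.5
1,monomolecular,b,2.9920
1,monomolecular,k,0.0163
1,bridges,W0,2.8732
1,bridges,a,108.1
1,bridges,k,0.00002
1,bridges,m,1.9516
1,janoschek,a,110.9
1,janoschek,W0,2.8732
1,janoschek,k,0.00002
1,janoschek,m,1.9516
1,logistic,a,104.5
1,logistic,b,19.9255
1,logistic,k,0.0163
1,von_bertalanffy,a,131.0
1,von_bertalanffy,b,0.8580
1,von_bertalanffy,k,0.00656
1,richards,a,116.5
1,richards,b,0.3656
1,richards,k,0.00964
1,richards,m,0.0776
1,weibull,a,110.9
1,weibull,b,2.8732
1,weibull,k,1.9516
1,weibull,IP,161.0
1,sinusoidal,y0,49.3647
1,sinusoidal,a,51.3537
1,sinusoidal,b,843.2
1,sinusoidal,c,4.9835
2,monomolecular,a,101.6
2,monomolecular,b,2.6014
2,monomolecular,k,0.0167
2,logistic,a,101.6
2,logistic,b,13.4828
2,logistic,k,0.0167
2,von_bertalanffy,a,115.5
2,von_bertalanffy,b,0.7968
2,von_bertalanffy,k,0.00802
2,weibull,a,112.9
2,weibull,k,1.4904
2,weibull,IP,98.9849
2,sinusoidal,y0,27.3143
2,sinusoidal,a,73.0858
2,sinusoidal,b,1178.1
2,sinusoidal,c,5.8046
3,monomolecular,a,140.6
3,monomolecular,b,2.4877
3,monomolecular,k,0.0154
3,logistic,a,140.6
3,logistic,b,12.0333
3,logistic,k,0.0154
3,von_bertalanffy,a,162.3
3,von_bertalanffy,b,0.7723
3,von_bertalanffy,k,0.00739
3,weibull,a,-0.9938
3,weibull,k,-0.5283
3,weibull,IP,68.2845
3,sinusoidal,y0,81.2345
3,sinusoidal,a,14.7996
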