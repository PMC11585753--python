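dataset,model,statistic,value
1,monomolecular,r2_adj,0.9974
1,bridges,r2_adj,0.9995
1,janoschek,r2_adj,0.9995
1,logistic,r2_adj,0.9974
1,von_bertalanffy,r2_adj,0.9987
1,richards,r2_adj,0.9995
1,schumacher,r2_adj,0.9993
1,morgan,r2_adj,0.9997
1,chanter,r2_adj,0.9996
1,weibull,r2_adj,0.9995
1,sinusoidal,r2_adj,0.9998
1,monomolecular,dw,0.6642
1,bridges,dw,1.7864
1,janoschek,dw,1.7864
1,logistic,dw,0.6640
1,von_bertalanffy,dw,1.0101
1,richards,dw,1.6731
1,schumacher,dw,1.3309
1,morgan,dw,1.3687
1,chanter,dw,1.7562
1,weibull,dw,1.7864
1,sinusoidal,dw,2.0012
1,monomolecular,shapiro_p,0.0331
1,bridges,shapiro_p,0.3792
1,janoschek,shapiro_p,0.3795
1,logistic,shapiro_p,0.0329
1,von_bertalanffy,shapiro_p,0.2579
1,richards,shapiro_p,0.8534
1,schumacher,shapiro_p,0.6896
1,morgan,shapiro_p,0.6690
1,chanter,shapiro_p,0.6852
1,weibull,shapiro_p,0.3786
1,sinusoidal,shapiro_p,0.3102
1,monomolecular,white_p,0.1633
1,bridges,white_p,0.6002
1,janoschek,white_p,0.6256
1,logistic,white_p,0.1633
1,von_bertalanffy,white_p,0.2883
1,richards,white_p,0.3488
1,schumacher,white_p,0.6435
1,morgan,white_p,0.2971
1,chanter,white_p,0.3236
1,weibull,white_p,0.4417
1,sinusoidal,white_p,0.3092
1,monomolecular,rmse,1.7628
1,bridges,rmse,0.7461
1,janoschek,rmse,0.7461
1,logistic,rmse,1.7628
1,von_bertalanffy,rmse,1.2149
1,richards,rmse,0.8019
1,schumacher,rmse,0.9004
1,morgan,rmse,0.6321
1,chanter,rmse,0.7044
1,weibull,rmse,0.7461
1,sinusoidal,rmse,0.5062
1,monomolecular,aic,45.9725
1,bridges,aic,25.9232
1,janoschek,aic,25.9232
1,logistic,aic,45.9725
1,von_bertalanffy,aic,37.0386
1,richards,aic,27.6561
1,schumacher,aic,29.8482
1,morgan,aic,21.3595
1,chanter,aic,24.5443
1,weibull,aic,25.9232
1,sinusoidal,aic,16.6123
1,monomolecular,bic,17.6083
1,bridges,bic,-1.9561
1,janoschek,bic,-1.9561
1,logistic,bic,17.6083
1,von_bertalanffy,bic,8.6745
1,richards,bic,-0.2232
1,schumacher,bic,1.4841
1,morgan,bic,-7.0046
1,chanter,bic,-3.3350
1,weibull,bic,-1.9561
1,sinusoidal,bic,-11.2629
2,monomolecular,r2_adj,0.9912
2,bridges,r2_adj,0.9982
2,janoschek,r2_adj,0.9982
2,logistic,r2_adj,0.9912
2,von_bertalanffy,r2_adj,0.9979
2,richards,r2_adj,0.9978
2,schumacher,r2_adj,0.9976
2,morgan,r2_adj,0.9985
2,chanter,r2_adj,0.9965
2,weibull,r2_adj,0.9982
2,sinusoidal,r2_adj,0.9991
2,monomolecular,dw,0.8717
2,bridges,dw,1.4102
2,janoschek,dw,1.4103
2,logistic,dw,0.8715
2,von_bertalanffy,dw,1.4022
2,richards,dw,1.3224
2,schumacher,dw,1.3894
2,morgan,dw,1.5448
2,chanter,dw,1.2871
2,weibull,dw,1.4102
2,sinusoidal,dw,2.0976
2,monomolecular,shapiro_p,0.1899
2,bridges,shapiro_p,0.9647
2,janoschek,shapiro_p,0.9648
2,logistic,shapiro_p,0.1890
2,von_bertalanffy,shapiro_p,0.8781
2,richards,shapiro_p,0.9815
2,schumacher,shapiro_p,0.5500
2,morgan,shapiro_p,0.4799
2,chanter,shapiro_p,0.6051
2,weibull,shapiro_p,0.9648
2,sinusoidal,shapiro_p,0.5243
2,monomolecular,white_p,0.1537
2,bridges,white_p,0.9867
2,janoschek,white_p,0.9855
2,logistic,white_p,0.1537
2,von_bertalanffy,white_p,0.9036
2,richards,white_p,0.9850
2,schumacher,white_p,0.2435
2,morgan,white_p,0.2845
2,chanter,white_p,0.1595
2,weibull,white_p,0.9853
2,sinusoidal,white_p,0.9502
2,monomolecular,rmse,3.0898
2,bridges,rmse,1.3897
2,janoschek,rmse,1.3897
2,logistic,rmse,3.0898
2,von_bertalanffy,rmse,1.5132
2,richards,rmse,1.5450
2,schumacher,rmse,1.6194
2,morgan,rmse,1.2686
2,chanter,rmse,1.9602
2,weibull,rmse,1.3897
2,sinusoidal,rmse,0.9665
2,monomolecular,aic,59.4411
2,bridges,aic,40.8511
2,janoschek,aic,40.8511
2,logistic,aic,59.4412
2,von_bertalanffy,aic,42.3082
2,richards,aic,43.3937
2,schumacher,aic,43.9360
2,morgan,aic,38.0774
2,chanter,aic,49.1069
2,weibull,aic,40.8511
2,sinusoidal,aic,32.1362
2,monomolecular,bic,31.0770
2,bridges,bic,12.9718
2,janoschek,bic,12.9718
2,logistic,bic,31.0770
2,von_bertalanffy,bic,13.9440
2,richards,bic,15.5144
2,schumacher,bic,15.5719
2,morgan,bic,9.7132
2,chanter,bic,21.2276
2,weibull,bic,12.9718
2,sinusoidal,bic,4.2569
3,monomolecular,r2_adj,0.9746
3,bridges,r2_adj,0.9952
3,janoschek,r2_adj,0.9952
3,logistic,r2_adj,0.9746
3,von_bertalanffy,r2_adj,0.9917
3,richards,r2_adj,0.9953
3,schumacher,r2_adj,0.9892
3,morgan,r2_adj,0.9907
3,chanter,r2_adj,0.9867
3,weibull,r2_adj,0.9962
3,sinusoidal,r2_adj,-0.2942
3,monomolecular,dw,0.6579
3,bridges,dw,1.5884
3,janoschek,dw,1.5880
3,logistic,dw,0.6580
3,von_bertalanffy,dw,0.8646
3,richards,dw,1.4966
3,schumacher,dw,0.7998
3,morgan,dw,0.8253
3,chanter,dw,0.7739
3,weibull,dw,1.4114
3,sinusoidal,dw,0.2117
3,monomolecular,shapiro_p,0.7560
3,bridges,shapiro_p,0.5819
3,janoschek,shapiro_p,0.5816
3,logistic,shapiro_p,0.7558
3,von_bertalanffy,shapiro_p,0.3830
3,richards,shapiro_p,0.6450
3,schumacher,shapiro_p,0.2054
3,morgan,shapiro_p,0.4220
3,chanter,shapiro_p,0.3105
3,weibull,shapiro_p,0.5772
3,sinusoidal,shapiro_p,0.1142
3,monomolecular,white_p,0.1886
3,bridges,white_p,0.3522
3,janoschek,white_p,0.2843
3,logistic,white_p,0.1888
3,von_bertalanffy,white_p,0.2254
3,richards,white_p,0.3337
3,schumacher,white_p,0.5659
3,morgan,white_p,0.1071
3,chanter,white_p,0.2008
3,weibull,white_p,0.4233
3,sinusoidal,white_p,0.1678
3,monomolecular,rmse,7.1523
3,bridges,rmse,3.0994
3,janoschek,rmse,3.0994
3,logistic,rmse,7.1523
3,von_bertalanffy,rmse,4.0961
3,richards,rmse,3.0771
3,schumacher,rmse,4.6744
3,morgan,rmse,4.3411
3,chanter,rmse,5.1729
3,weibull,rmse,2.7675
3,sinusoidal,rmse,51.0935
3,monomolecular,aic,79.5852
3,bridges,aic,60.1027
3,janoschek,aic,60.1027
3,logistic,aic,79.5852
3,von_bertalanffy,aic,66.2074
3,richards,aic,59.9286
3,schumacher,aic,69.3741
3,morgan,aic,67.6013
3,chanter,aic,72.3973
3,weibull,aic,57.3838
3,sinusoidal,aic,127.3611
3,monomolecular,bic,51.2210
3,bridges,bic,32.2234
3,janoschek,bic,32.2234
3,logistic,bic,51.2210
3,von_bertalanffy,bic,37.8432
3,richards,bic,32.0494
3,schumacher,bic,41.0100
3,morgan,bic,39.2372
3,chanter,bic,44.5181
3,weibull,bic,29.5045
3,sinusoidal,bic,99.4818
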