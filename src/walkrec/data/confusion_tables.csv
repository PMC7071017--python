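table,method,classifier,n_patterns,tp,fp,tn,fn,sensitivity,specificity,accuracy
3,manual_selection,random_forests,,4708,19,500,237,0.9521,0.9634,0.9531
3,manual_selection,rbf_svm,,4703,19,500,242,0.9511,0.9634,0.9522
3,manual_selection,gbm,,4707,29,490,238,0.9519,0.9441,0.9511
3,manual_selection,knn_k5,,4723,48,471,222,0.9551,0.9075,0.9506
3,manual_selection,linear_svm,,4642,44,475,303,0.9387,0.9152,0.9365
3,manual_selection,naive_bayes,,4654,61,458,291,0.9412,0.8825,0.9356
3,manual_selection,c50,,4633,48,471,312,0.9369,0.9075,0.9341
3,deep_learning,cnn_a1,,4632,38,481,313,0.9359,0.9282,0.9357
3,deep_learning,cnn_a2,,4563,50,469,382,0.9210,0.9115,0.9210
3,deep_learning,cnn_b1,,4567,32,487,378,0.9251,0.9211,0.9250
3,deep_learning,cnn_b2,,4596,47,472,349,0.9276,0.9247,0.9275
3,deep_learning_oversampling,cnn_a1,,3100,3,3003,100,0.9834,0.9819,0.9834
3,deep_learning_oversampling,cnn_a2,,3080,17,3005,92,0.9824,0.9803,0.9824
3,deep_learning_oversampling,cnn_b1,,3098,5,3019,84,0.9857,0.9853,0.9857
3,deep_learning_oversampling,cnn_b2,,3069,28,3016,81,0.9824,0.9830,0.9824
4,svm_support_vectors,rbf_svm,1551,4724,33,486,221,0.9553,0.9364,0.9535
4,svm_support_vectors,rbf_svm,221,4611,121,398,334,0.9325,0.7669,0.9167
4,svm_support_vectors,rbf_svm,5,4586,126,393,359,0.9274,0.7572,0.9112
4,svm_support_vectors,random_forests,1551,4674,35,484,271,0.9452,0.9326,0.9440
4,svm_support_vectors,random_forests,221,4573,75,444,372,0.9248,0.8555,0.9182
4,svm_support_vectors,random_forests,5,4378,109,410,567,0.8853,0.7900,0.8763
4,svm_support_vectors,gbm,1551,4668,37,482,277,0.9440,0.9287,0.9425
4,svm_support_vectors,gbm,221,4547,82,437,398,0.9195,0.8420,0.9122
4,svm_support_vectors,gbm,5,4497,116,403,448,0.9094,0.7765,0.8968
4,svm_support_vectors,linear_svm,1551,4621,37,482,324,0.9345,0.9287,0.9339
4,svm_support_vectors,linear_svm,221,4449,52,467,496,0.8997,0.8998,0.8997
4,svm_support_vectors,linear_svm,5,4425,115,404,520,0.8948,0.7784,0.8838
4,svm_support_vectors,knn_k7,1551,4703,69,450,242,0.9511,0.8671,0.9431
4,svm_support_vectors,knn_k7,221,4563,68,41,382,0.9228,0.8690,0.9176
4,svm_support_vectors,knn_k7,5,4330,105,414,615,0.8756,0.7977,0.8682
4,svm_support_vectors,naive_bayes,1551,4660,146,373,285,0.9424,0.7187,0.9211
4,svm_support_vectors,naive_bayes,221,4607,132,387,338,0.9316,0.7457,0.9140
4,svm_support_vectors,naive_bayes,5,4541,123,396,404,0.9183,0.7630,0.9036
4,svm_support_vectors,c50,1551,4400,56,463,545,0.8898,0.8921,0.8900
4,svm_support_vectors,c50,221,4176,84,435,769,0.8445,0.8382,0.9439
4,svm_support_vectors,c50,5,4683,136,383,262,0.9470,0.7380,0.9272
4,pam_medoids,rbf_svm,180,4651,47,472,294,0.9405,0.9094,0.9376
4,pam_medoids,rbf_svm,10,4555,81,438,390,0.9211,0.8439,0.9138
4,pam_medoids,rbf_svm,4,4623,104,415,322,0.9349,0.7996,0.9220
4,pam_medoids,rbf_svm,2,4323,149,370,622,0.8742,0.7129,0.8589
4,pam_medoids,random_forests,180,4633,57,462,312,0.9369,0.8902,0.9325
4,pam_medoids,random_forests,10,4513,77,442,432,0.9126,0.8516,0.9068
4,pam_medoids,random_forests,4,4410,91,428,535,0.8918,0.8247,0.8854
4,pam_medoids,random_forests,2,3973,126,393,972,0.8034,0.7572,0.7990
4,pam_medoids,gbm,180,4598,53,466,347,0.9298,0.8979,0.9268
4,pam_medoids,gbm,10,4468,70,449,447,0.9035,0.8651,0.8999
4,pam_medoids,gbm,4,4500,94,425,445,0.9100,0.8189,0.9014
4,pam_medoids,gbm,2,4229,120,399,716,0.8552,0.7688,0.8470
4,pam_medoids,linear_svm,180,4511,38,481,434,0.9122,0.9268,0.9136
4,pam_medoids,linear_svm,10,4544,89,430,401,0.9189,0.8285,0.9103
4,pam_medoids,linear_svm,4,4496,123,396,449,0.9092,0.7630,0.8953
4,pam_medoids,linear_svm,2,4311,156,363,634,0.8718,0.6994,0.8554
4,pam_medoids,knn_k7,180,4629,66,453,316,0.9361,0.8728,0.9301
4,pam_medoids,knn_k7,10,4572,97,422,373,0.9246,0.8131,0.9140
4,pam_medoids,knn_k7,4,4434,92,425,445,0.9100,0.8189,0.9014
4,pam_medoids,knn_k7,2,4117,120,399,828,0.8326,0.7688,0.8265
4,pam_medoids,naive_bayes,180,4526,113,406,419,0.9153,0.7823,0.9026
4,pam_medoids,naive_bayes,10,4346,79,440,599,0.8789,0.8478,0.8759
4,pam_medoids,naive_bayes,4,4395,85,434,550,0.8888,0.8362,0.8838
4,pam_medoids,naive_bayes,2,4172,156,363,773,0.8437,0.6994,0.8300
4,pam_medoids,c50,180,4362,76,443,583,0.8821,0.8536,0.8794
4,pam_medoids,c50,10,4293,77,442,652,0.8681,0.8516,0.8666
4,pam_medoids,c50,4,4593,109,410,352,0.9288,0.7900,0.9156
4,pam_medoids,c50,2,4200,144,375,745,0.8493,0.7225,0.8373
4,exhaustive_search,rbf_svm,2,4492,93,426,453,0.9084,0.8208,0.9001
4,exhaustive_search,random_forests,2,4179,89,430,766,0.8451,0.8285,0.8435
4,exhaustive_search,gbm,2,4306,78,441,639,0.8708,0.8497,0.8688
4,exhaustive_search,linear_svm,2,4360,85,434,585,0.8817,0.8362,0.8774
4,exhaustive_search,knn_k7,2,4293,91,428,625,0.8681,0.8247,0.8640
4,exhaustive_search,naive_bayes,2,4135,91,428,810,0.8362,0.8247,0.8351
4,exhaustive_search,c50,2,4587,120,399,358,0.9276,0.7688,0.9125
4,bfs,rbf_svm,4,4526,68,451,419,0.9153,0.8690,0.9109
4,bfs,rbf_svm,10,4504,63,456,441,0.9108,0.8786,0.9078
4,bfs,random_forests,4,4441,68,451,504,0.8981,0.8690,0.8953
4,bfs,random_forests,10,4494,60,459,451,0.9088,0.8844,0.9065
4,bfs,gbm,4,4411,62,457,534,0.8920,0.8805,0.8909
4,bfs,gbm,10,4465,64,455,480,0.9029,0.8767,0.9004
4,bfs,linear_svm,4,4376,66,453,569,0.8849,0.8728,0.8838
4,bfs,linear_svm,10,4443,69,450,502,0.8985,0.8671,0.8955
4,bfs,knn_k7,4,4434,75,444,511,0.8967,0.8555,0.8928
4,bfs,knn_k7,10,4430,74,445,515,0.8959,0.8574,0.8922
4,bfs,naive_bayes,4,4623,130,389,322,0.9349,0.7495,0.9173
4,bfs,naive_bayes,10,4645,110,409,300,0.9393,0.7881,0.9250
4,bfs,c50,4,4404,86,433,541,0.8906,0.8343,0.8852
4,bfs,c50,10,4382,64,455,563,0.8861,0.8767,0.8852
4,sa,rbf_svm,4,4656,121,398,289,0.9416,0.7669,0.9250
4,sa,rbf_svm,10,4532,92,427,413,0.9165,0.8227,0.9076
4,sa,random_forests,4,4414,95,424,531,0.8926,0.8170,0.8854
4,sa,random_forests,10,4496,72,447,449,0.9092,0.8613,0.9046
4,sa,gbm,4,4524,110,409,421,0.9128,0.7881,0.9028
4,sa,gbm,10,4441,83,436,504,0.8981,0.8401,0.8926
4,sa,linear_svm,4,4553,124,395,392,0.9207,0.7611,0.9056
4,sa,linear_svm,10,4384,85,434,561,0.8866,0.8362,0.8818
4,sa,knn_k7,4,4443,114,405,502,0.8985,0.7803,0.8873
4,sa,knn_k7,10,4471,98,421,747,0.9041,0.8112,0.8953
4,sa,naive_bayes,4,4546,142,377,399,0.9193,0.7264,0.9010
4,sa,naive_bayes,10,4595,135,384,350,0.9292,0.7399,0.9112
4,sa,c50,4,4413,101,418,535,0.8924,0.8054,0.8842
4,sa,c50,10,4134,71,448,811,0.8360,0.8632,0.8386
5,ensemble,top_rbf_svm,,4766,30,489,179,0.9638,0.9422,0.9617
5,ensemble,top_c50,,4746,24,495,199,0.9598,0.9538,0.9592
5,ensemble,logistic_wa,,4708,19,500,237,0.9521,0.9634,0.9531
5,ensemble,top_naive_bayes,,4539,8,511,406,0.9179,0.9846,0.9242
5,ensemble,top_linear_svm,,4441,9,510,504,0.8981,0.9827,0.9061
5,ensemble,top_gbm,,4426,9,510,519,0.8950,0.9827,0.9034
5,ensemble,top_random_forests,,4419,7,512,526,0.8936,0.9865,0.9025
5,ensemble,top_knn_k9,,4418,9,510,527,0.8934,0.9827,0.9019
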