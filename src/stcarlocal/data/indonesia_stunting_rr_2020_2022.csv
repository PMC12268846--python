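area,time,ls,rr
Aceh,2020,4,1.227
Aceh,2021,3,1.270
Aceh,2022,3,0.956
Bali,2020,4,0.861
Bali,2021,3,0.523
Bali,2022,4,0.533
Bangka Belitung,2020,2,0.302
Bangka Belitung,2021,3,0.625
Bangka Belitung,2022,3,0.467
Banten,2020,3,0.449
Banten,2021,3,0.702
Banten,2022,4,0.817
Bengkulu,2020,3,0.762
Bengkulu,2021,3,0.670
Bengkulu,2022,3,0.577
Gorontalo,2020,3,1.009
Gorontalo,2021,3,0.899
Gorontalo,2022,3,0.895
DKI Jakarta,2020,1,0.004
DKI Jakarta,2021,2,0.338
DKI Jakarta,2022,2,0.149
Jambi,2020,3,0.695
Jambi,2021,2,0.317
Jambi,2022,3,0.486
Jawa Barat,2020,4,0.825
Jawa Barat,2021,4,0.872
Jawa Barat,2022,4,0.821
Jawa Tengah,2020,4,1.201
Jawa Tengah,2021,4,0.951
Jawa Tengah,2022,4,1.123
Jawa Timur,2020,4,1.060
Jawa Timur,2021,4,1.126
Jawa Timur,2022,4,1.133
Kalimantan Barat,2020,5,2.519
Kalimantan Barat,2021,5,2.215
Kalimantan Barat,2022,5,1.947
Kalimantan Selatan,2020,4,1.202
Kalimantan Selatan,2021,5,1.094
Kalimantan Selatan,2022,4,1.116
Kalimantan Tengah,2020,5,2.039
Kalimantan Tengah,2021,4,1.140
Kalimantan Tengah,2022,4,1.212
Kalimantan Timur,2020,4,1.332
Kalimantan Timur,2021,5,1.248
Kalimantan Timur,2022,5,1.619
Kalimantan Utara,2020,5,2.637
Kalimantan Utara,2021,5,1.948
Kalimantan Utara,2022,5,1.962
Kepulauan Riau,2020,4,0.844
Kepulauan Riau,2021,3,0.795
Kepulauan Riau,2022,3,0.585
Lampung,2020,2,0.487
Lampung,2021,3,0.642
Lampung,2022,3,0.540
Maluku,2020,4,0.763
Maluku,2021,3,0.716
Maluku,2022,3,1.181
Maluku Utara,2020,3,0.852
Maluku Utara,2021,4,1.370
Maluku Utara,2022,4,1.467
Nusa Tenggara Barat,2020,5,1.853
Nusa Tenggara Barat,2021,5,2.290
Nusa Tenggara Barat,2022,5,2.221
Nusa Tenggara Timur,2020,5,2.421
Nusa Tenggara Timur,2021,4,2.384
Nusa Tenggara Timur,2022,4,2.676
Papua,2020,2,0.610
Papua,2021,3,1.067
Papua,2022,3,1.009
Papua Barat,2020,3,1.220
Papua Barat,2021,3,1.388
Papua Barat,2022,4,1.516
Riau,2020,3,0.707
Riau,2021,3,0.635
Riau,2022,3,0.498
Sulawesi Barat,2020,5,2.084
Sulawesi Barat,2021,5,2.038
Sulawesi Barat,2022,5,2.768
Sulawesi Selatan,2020,4,1.092
Sulawesi Selatan,2021,4,1.099
Sulawesi Selatan,2022,4,1.081
Sulawesi Tengah,2020,4,1.260
Sulawesi Tengah,2021,4,1.394
Sulawesi Tengah,2022,4,1.571
Sulawesi Tenggara,2020,4,1.536
Sulawesi Tenggara,2021,4,1.945
Sulawesi Tenggara,2022,4,1.321
Sulawesi Utara,2020,3,0.489
Sulawesi Utara,2021,2,0.311
Sulawesi Utara,2022,2,0.276
Sumatera Barat,2020,5,1.609
Sumatera Barat,2021,5,1.591
Sumatera Barat,2022,5,1.235
Sumatera Selatan,2020,2,0.208
Sumatera Selatan,2021,2,0.463
Sumatera Selatan,2022,2,0.370
Sumatera Utara,2020,3,0.627
Sumatera Utara,2021,4,0.706
Sumatera Utara,2022,3,0.658
DI Yogyakarta,2020,4,1.095
DI Yogyakarta,2021,4,1.112
DI Yogyakarta,2022,4,1.097
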