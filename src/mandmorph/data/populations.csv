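prefecture,population,environment,latitude,longitude,n_female,n_male,n_young
Aomori,Shimokita,wild,41.51,140.93,4,4,0
Miyagi,Kinkazan,wild,38.29,141.57,5,2,0
Toyama,Hakusan,wild,36.29,136.64,9,9,0
Saitama,Nagatoro,captive,36.11,139.11,1,1,0
Nagano,Kamimatsu,wild,35.78,137.69,1,0,0
Nagano,Matsukawa,wild,35.60,137.91,0,1,0
Nagano,Takamori,wild,35.55,137.88,1,0,0
Fukui,Takahama,captive,35.49,135.55,19,13,10
Fukui,WakasaF,wild,35.49,135.75,6,6,3
Aichi,Inuyama,captive,35.38,136.94,1,0,0
Shimane,WakasaS,captive,35.34,134.40,12,9,0
Shimane,Mitoya,wild,35.30,132.89,1,0,0
Shimane,Kotsugu,wild,35.29,132.91,1,1,1
Shimane,Yoshida,wild,35.17,132.85,0,1,0
Kyoto,Arashiyama,captive,35.01,135.67,9,4,2
Shiga,Koga,wild,34.97,136.17,10,5,1
Shimane,Hasumi,wild,34.87,132.62,4,4,2
Shizuoka,Izu,captive,34.86,138.94,4,1,1
Osaka,Minoo,captive,34.85,135.47,1,1,0
Kagawa,Shodoshima,captive,34.51,134.30,1,0,0
Hiroshima,Miyajima,captive,34.28,132.31,4,5,0
Wakayama,Noguchi,wild,33.90,135.18,0,1,0
Kagoshima,Yakushima,both,30.29,130.44,7,8,5
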