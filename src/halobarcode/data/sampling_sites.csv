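site_no,province,site_name,lon_dms,lat_dms
1,Alborz,Jafar Abad,50° 49′ 26.511″,35° 42′ 38.401″
2,Alborz,Eshtehard,50° 30′ 20.195″,35° 44′ 45.052″
3,Markazi,Meyghan,49° 48′ 56.527″,34° 10′ 12.262″
4,Markazi,Delijan,50° 49′ 58.401″,33° 48′ 38.401″
5,Isfahan,Varzaneh,52° 39′ 53.002″,32° 25′ 22.763″
6,Mazandaran,Chapak roud,52° 51′ 48.51″,36° 43′ 9.602″
7,West-Azerbayjan,Gulmanxana,45° 16′ 17.644″,37° 35′ 13.912″
8,West-Azerbayjan,Talatappe,45° 13′ 27.699″,37° 44′ 54.563″
9,Qom,Qom highway,51° 10′ 43.625″,35° 19′ 18.318″
10,Sistan & Blaochestan,Chabahar,60° 40′ 20.423″,25° 17′ 21.001″
11,Sistan & Blaochestan,Gwadr,62° 22′ 29.560″,25° 20′ 6.936″
12,Tehran,Robat Karim,50° 57′ 44.412″,35° 26′ 37.730″
13,Tehran,Varamin,51° 17′ 40.124″,34° 56′ 53.952″
14,Golestan,Bandar Torkamen,54° 3′ 0.072″,36° 53′ 18.160″
15,Golestan,Aq Qala,54° 22′ 46.480″,37° 5′ 58.844″
16,Boshehr,Dayyer,51° 58′ 31.501″,27° 50′ 31.642″
17,Boshehr,Helleh,50° 49′ 52.812″,29° 11′ 22.106″
18,East-Azerbayjan,Nazarkahrizi,46° 54′ 52.339″,37° 21′ 34.416″
19,East-Azerbayjan,Qushchi,45° 4′ 39.946″,37° 59′ 40.941″
20,East-Azerbayjan,Sharafkhaneh,45° 28′ 33.041″,38° 10′ 2.236″
21,East-Azerbayjan,SarayDeh,45° 38′ 48.551″,37° 52′ 47.262″
22,East-Azerbayjan,Qareh Qeshlaq,45° 58′ 6.110″,37° 13′ 46.699″
23,Fars,Tashk,53° 35′ 41.686″,29° 49′ 15.232″
24,Fars,Maharlu,53° 45′ 50.043″,29° 31′ 45.922″
25,Kerman,Nogh,56° 0′ 0219″,30° 39′ 17.028″
26,Kerman,Shahrbabak,54° 39′ 56.807″,30° 6′ 8.463″
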