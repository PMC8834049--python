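case_id,site,subsite,age,sex,positive_rate
1,stomach,Pyloric gland,64,M,0.953
2,stomach,Pyloric gland,81,M,0.842
3,stomach,Fundic glands,55,M,0.5
4,stomach,Pyloric gland,83,F,0.166
5,stomach,Cardiac gland,83,M,0.379
6,stomach,Fundic glands,66,M,0.894
7,stomach,Fundic glands,63,M,0.192
8,stomach,Cardiac gland,58,F,0.272
1,duodenum,Bulb of duodenum,64,M,0.52
2,duodenum,Bulb of duodenum,81,M,0.16
4,duodenum,Bulb of duodenum,83,F,0.333
5,duodenum,Bulb of duodenum,83,M,0.208
8,duodenum,Bulb of duodenum,58,F,0.6
9,duodenum,Bulb of duodenum,73,M,0.538
10,duodenum,Bulb of duodenum,69,F,0.5
11,duodenum,Second portion,67,M,0.187
12,duodenum,Second portion,71,F,0.041
13,duodenum,Second portion,79,M,0.218
14,duodenum,Second portion,55,M,0.185
15,duodenum,Second portion,67,M,0.346
16,duodenum,Second portion,69,M,0.478
17,duodenum,Second portion,73,M,0.313
18,rectum,,60,F,0
19,rectum,,83,F,0.3
20,rectum,,52,M,0
21,rectum,,70,F,0
22,rectum,,40,M,0
23,rectum,,62,M,0.1
24,rectum,,51,F,0
25,rectum,,81,F,0.2
26,rectum,,75,M,0
27,rectum,,70,F,0.043
28,rectum,,56,F,0.043
29,rectum,,87,F,0
30,rectum,,79,F,0
31,rectum,,77,M,0.058
32,rectum,,37,M,0
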