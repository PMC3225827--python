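{
 "rk-tauleap-s3-eps0.1": {
  "s": 3,
  "eps": 0.1,
  "r": [
   1.0,
   0.33281071341443985,
   0.04240393928593766
  ],
  "l": 3.9455681616781
 },
 "rk-tauleap-s3-eps0.25": {
  "s": 3,
  "eps": 0.25,
  "r": [
   1.0,
   0.275380997722564,
   0.025615587305548856
  ],
  "l": 5.895765193535658
 },
 "rk-tauleap-s3-eps0.5": {
  "s": 3,
  "eps": 0.5,
  "r": [
   1.0,
   0.23448361907439885,
   0.016919230450211344
  ],
  "l": 8.120211654287534
 },
 "rk-tauleap-s5-eps0.1": {
  "s": 5,
  "eps": 0.1,
  "r": [
   1.0,
   0.35234063677875666,
   0.06608900084662306,
   0.005873327516659948,
   0.00019515645659239683
  ],
  "l": 10.718574942375751
 },
 "rk-tauleap-s5-eps0.25": {
  "s": 5,
  "eps": 0.25,
  "r": [
   1.0,
   0.29540580561822155,
   0.04157310816336761,
   0.002656095690846322,
   6.236567776262142e-05
  ],
  "l": 15.431874927696672
 },
 "rk-tauleap-s5-eps0.5": {
  "s": 5,
  "eps": 0.5,
  "r": [
   1.0,
   0.2531627428096249,
   0.02799023876821098,
   0.0013605493519404763,
   2.3977589339919403e-05
  ],
  "l": 20.939721334421275
 }
}
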