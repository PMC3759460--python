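{
 "0.5_15_3": [
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.11050660007135213,
  0.0,
  0.09124152693542632,
  0.0008027113806635748,
  0.0035676061362825543,
  0.007937923653228684,
  0.020870495897252945,
  0.12442026400285408,
  0.022743489118801283,
  0.08749554049232965,
  0.015608276846236176,
  0.13191223688904746,
  0.014805565465572601,
  0.04459507670353193,
  0.07268997502675704,
  0.03077060292543703,
  0.03540849090260435,
  0.03888690688547984,
  0.11737424188369604,
  0.028362468783446306
 ],
 "1_12_3": [
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.16334871456822678,
  0.13605800922874092,
  0.017007251153592615,
  0.21476598549769282,
  0.16295319709953857,
  0.21806196440342782,
  0.08780487804878048
 ],
 "0.5_15_5": [
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.15907305577376277,
  0.027690494893951294,
  0.16692851531814612,
  0.0007855459544383347,
  0.0877847604084839,
  0.014728986645718775,
  0.06893165750196387,
  0.12313432835820895,
  0.040455616653574236,
  0.06304006284367636,
  0.07109190887666929,
  0.11390416339355852,
  0.0624509033778476
 ]
}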