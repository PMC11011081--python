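{
  "class_names": [
    "activity",
    "chasing",
    "mounting",
    "feeding",
    "resting",
    "disturbance"
  ],
  "clips": {
    "activity/activity_0000": 1826701614,
    "activity/activity_0001": 1367864806,
    "activity/activity_0002": 1097657231,
    "activity/activity_0003": 579362555,
    "activity/activity_0004": 661058651,
    "activity/activity_0005": 87989972,
    "activity/activity_0006": 161576974,
    "activity/activity_0007": 35492826,
    "activity/activity_0008": 376383645,
    "activity/activity_0009": 1746484539,
    "activity/activity_0010": 1394609702,
    "activity/activity_0011": 1960127675,
    "activity/activity_0012": 1081530686,
    "activity/activity_0013": 1302740407,
    "activity/activity_0014": 2084654369,
    "activity/activity_0015": 1566581934,
    "activity/activity_0016": 1357791198,
    "activity/activity_0017": 1167425778,
    "activity/activity_0018": 1202413557,
    "activity/activity_0019": 2008052738,
    "chasing/chasing_0000": 595598245,
    "chasing/chasing_0001": 1752032165,
    "chasing/chasing_0002": 1440696407,
    "chasing/chasing_0003": 5880883,
    "chasing/chasing_0004": 846428919,
    "chasing/chasing_0005": 1841261662,
    "chasing/chasing_0006": 1190382222,
    "chasing/chasing_0007": 72124473,
    "chasing/chasing_0008": 1642588603,
    "chasing/chasing_0009": 1566923138,
    "chasing/chasing_0010": 1818006482,
    "chasing/chasing_0011": 377217572,
    "chasing/chasing_0012": 191741830,
    "chasing/chasing_0013": 1853662620,
    "chasing/chasing_0014": 47463574,
    "chasing/chasing_0015": 1162779115,
    "chasing/chasing_0016": 172656923,
    "chasing/chasing_0017": 643626383,
    "chasing/chasing_0018": 1033071480,
    "chasing/chasing_0019": 907713895,
    "disturbance/disturbance_0000": 860813095,
    "disturbance/disturbance_0001": 1690280743,
    "disturbance/disturbance_0002": 679605935,
    "disturbance/disturbance_0003": 514041964,
    "disturbance/disturbance_0004": 1700138881,
    "disturbance/disturbance_0005": 1882235552,
    "disturbance/disturbance_0006": 170294837,
    "disturbance/disturbance_0007": 125773896,
    "disturbance/disturbance_0008": 1441526998,
    "disturbance/disturbance_0009": 721805890,
    "disturbance/disturbance_0010": 1231901275,
    "disturbance/disturbance_0011": 322722697,
    "disturbance/disturbance_0012": 1846923786,
    "disturbance/disturbance_0013": 967096425,
    "disturbance/disturbance_0014": 1921983830,
    "disturbance/disturbance_0015": 1710093347,
    "disturbance/disturbance_0016": 1514711733,
    "disturbance/disturbance_0017": 495300371,
    "disturbance/disturbance_0018": 1647140547,
    "disturbance/disturbance_0019": 111714892,
    "feeding/feeding_0000": 1804554973,
    "feeding/feeding_0001": 1478428095,
    "feeding/feeding_0002": 1511830742,
    "feeding/feeding_0003": 835202397,
    "feeding/feeding_0004": 1879383516,
    "feeding/feeding_0005": 290117534,
    "feeding/feeding_0006": 1243185673,
    "feeding/feeding_0007": 1549384411,
    "feeding/feeding_0008": 1815655708,
    "feeding/feeding_0009": 1128189815,
    "feeding/feeding_0010": 806201099,
    "feeding/feeding_0011": 666239354,
    "feeding/feeding_0012": 908297867,
    "feeding/feeding_0013": 1043323488,
    "feeding/feeding_0014": 1543657888,
    "feeding/feeding_0015": 1910160578,
    "feeding/feeding_0016": 156652360,
    "feeding/feeding_0017": 2005843176,
    "feeding/feeding_0018": 1141051469,
    "feeding/feeding_0019": 768359333,
    "mounting/mounting_0000": 865948037,
    "mounting/mounting_0001": 60816030,
    "mounting/mounting_0002": 11494707,
    "mounting/mounting_0003": 266896303,
    "mounting/mounting_0004": 17790419,
    "mounting/mounting_0005": 1440154963,
    "mounting/mounting_0006": 1128755548,
    "mounting/mounting_0007": 1389828892,
    "mounting/mounting_0008": 552547096,
    "mounting/mounting_0009": 1321529463,
    "mounting/mounting_0010": 1640795441,
    "mounting/mounting_0011": 823941273,
    "mounting/mounting_0012": 989821580,
    "mounting/mounting_0013": 2141492029,
    "mounting/mounting_0014": 1728701086,
    "mounting/mounting_0015": 2106327850,
    "mounting/mounting_0016": 815020182,
    "mounting/mounting_0017": 1472190200,
    "mounting/mounting_0018": 2040324894,
    "mounting/mounting_0019": 1396850658,
    "resting/resting_0000": 1444696807,
    "resting/resting_0001": 1227350964,
    "resting/resting_0002": 546762614,
    "resting/resting_0003": 691209253,
    "resting/resting_0004": 1545136976,
    "resting/resting_0005": 1276249595,
    "resting/resting_0006": 1083230752,
    "resting/resting_0007": 725658830,
    "resting/resting_0008": 1633503581,
    "resting/resting_0009": 840995399,
    "resting/resting_0010": 704750836,
    "resting/resting_0011": 1911849612,
    "resting/resting_0012": 566779217,
    "resting/resting_0013": 487817217,
    "resting/resting_0014": 1533673821,
    "resting/resting_0015": 1338284201,
    "resting/resting_0016": 104252791,
    "resting/resting_0017": 180421576,
    "resting/resting_0018": 809899613,
    "resting/resting_0019": 1788089690
  },
  "counts": {
    "activity": 20,
    "chasing": 20,
    "disturbance": 20,
    "feeding": 20,
    "mounting": 20,
    "resting": 20
  },
  "params": {
    "agent_intensity": 0.7,
    "agent_radius": 6.0,
    "background_intensity": 0.12,
    "disturbance_intensity": 1.0,
    "disturbance_scale": 2.2,
    "follow_jitter": 0.6,
    "follow_lag": 4,
    "frame_size": [
      64,
      64
    ],
    "frames_per_clip": 32,
    "noise_sigma": 0.01568627450980392,
    "overlap_fraction": 0.6,
    "speed": 2.0,
    "trough": [
      0.2,
      0.8
    ],
    "turn_sigma": 0.12
  },
  "seed": 0
}
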