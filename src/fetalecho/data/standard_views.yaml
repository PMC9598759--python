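# Preset probe poses (image->heart, 4x4 row-major) for the
# standard fetal echocardiography views and the lesion-
# sensitive views of the two pathology cases, designed on
# the default procedural hearts.  Regenerate with
# scripts/make_view_library.py.
views:
  four_chamber:
    pose: &id001
    - -0.8511017457758678
    - 0.4398653543345096
    - -0.2866082489975588
    - -11.816058942268333
    - -2.7755575615628914e-17
    - 0.5459196638573436
    - 0.8378375263819858
    - -11.78578693039507
    - 0.5250007793682503
    - 0.7130849813802428
    - -0.4646331789623603
    - -22.341938624022287
    - 0.0
    - 0.0
    - 0.0
    - 1.0
    required: &id002
    - LA
    - LV
    - RA
    - RV
  lvot:
    pose:
    - -0.6813280842466702
    - -0.19014230016959968
    - -0.7068507249080078
    - 10.349801997163315
    - -0.6808349093963892
    - -0.19000466691685933
    - 0.707362744775991
    - 7.347840166226383
    - -0.268804515892075
    - 0.9631947530152078
    - 0.0
    - -28.322763079650954
    - 0.0
    - 0.0
    - 0.0
    - 1.0
    required:
    - AO
    - LV
  rvot:
    pose:
    - 0.8149924967552398
    - 0.12598157791190107
    - 0.5656110609416051
    - -7.261806342582252
    - 0.5589721684947186
    - 0.08640594370643687
    - -0.8246721334812472
    - -3.5516951018096306
    - -0.15276565412739979
    - 0.9882624423294794
    - 0.0
    - -29.058258248871585
    - 0.0
    - 0.0
    - 0.0
    - 1.0
    required:
    - PA
    - RV
  three_vessel:
    pose:
    - 1.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 1.0
    - 0.0
    - -26.0
    - 0.0
    - 0.0
    - 1.0
    - 6.5
    - 0.0
    - 0.0
    - 0.0
    - 1.0
    required:
    - AO
    - PA
    - SVC
  three_vessel_trachea:
    pose:
    - 1.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 1.0
    - 0.0
    - -24.0
    - 0.0
    - 0.0
    - 1.0
    - 8.7
    - 0.0
    - 0.0
    - 0.0
    - 1.0
    required:
    - AO
    - DA
    - PA
    - SVC
    - Trachea
  aortic_arch:
    pose:
    - -0.08971883628160968
    - -0.07987824919293818
    - -0.9927587802291877
    - 4.305913167948475
    - 0.46771350537290873
    - 0.876652216415599
    - -0.11280500142016678
    - -18.627384367506192
    - 0.8793148510676139
    - -0.4744474225448892
    - -0.041292080747421536
    - 25.535876498691238
    - 0.0
    - 0.0
    - 0.0
    - 1.0
    required:
    - AO
    - Arch
    - DAO
  ductal:
    pose:
    - 0.2097592106373724
    - 0.3172277924988656
    - -0.9248608550582532
    - -8.743548444724228
    - 0.38599973357634065
    - 0.8422057905957998
    - 0.37642211938978537
    - -17.929846091435042
    - 0.8983347256072096
    - -0.4359540502773204
    - 0.05421057844202632
    - 20.154689443310712
    - 0.0
    - 0.0
    - 0.0
    - 1.0
    required:
    - DA
    - DAO
    - PA
  bicaval:
    pose:
    - -0.5631133152009813
    - 0.03926404295638513
    - 0.825446381768119
    - -7.09878137468449
    - -0.81733976603724
    - 0.12087906317133217
    - -0.563332902412961
    - 1.6152506129655726
    - -0.12189791260538363
    - -0.9918904107901941
    - -0.035976546317149735
    - 30.35244843180588
    - 0.0
    - 0.0
    - 0.0
    - 1.0
    required:
    - IVC
    - RA
    - SVC
lesion_views:
  double_aortic_arch:
    ring_transverse:
      pose:
      - 1.0
      - 0.0
      - 0.0
      - 0.5
      - 0.0
      - 1.0
      - 0.0
      - -20.5
      - 0.0
      - 0.0
      - 1.0
      - 10.3
      - 0.0
      - 0.0
      - 0.0
      - 1.0
      required:
      - Trachea
      - lArch
      - rArch
      check: two_arch_regions
    ring_coronal:
      pose:
      - 1.0
      - 0.0
      - 0.0
      - 1.0
      - -0.0
      - 0.0
      - 1.0
      - 11.3
      - 0.0
      - -1.0
      - 0.0
      - 30.0
      - 0.0
      - 0.0
      - 0.0
      - 1.0
      required:
      - DAO
      - lArch
      - rArch
      check: arches_join_dao
  hrh_vsd_mga_pa:
    four_chamber_rv_small:
      pose: *id001
      required: *id002
      check: rv_smaller_than_lv
    vsd_channel:
      pose:
      - -0.9881327142809995
      - 0.0
      - -0.15360253568110369
      - 1.000016369114701
      - 0.0
      - 1.0
      - 0.0
      - -27.000008963015688
      - 0.15360253568110369
      - 0.0
      - -0.9881327142809995
      - -6.4196684849927745
      - 0.0
      - 0.0
      - 0.0
      - 1.0
      required:
      - LV
      - RV
      - VSD
      check: lv_rv_channel
    pa_origin:
      pose:
      - 0.3481224307908191
      - 0.23763327273757084
      - 0.9068303043394186
      - -10.079144600716091
      - 0.8752340977496162
      - 0.2641398147013901
      - -0.40521035577330766
      - -7.646243294214334
      - -0.3358214515433857
      - 0.9347516172639374
      - -0.11603174869727183
      - -25.46761725809128
      - 0.0
      - 0.0
      - 0.0
      - 1.0
      required:
      - PA
      - RV
      check: no_pa_rv_contact
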