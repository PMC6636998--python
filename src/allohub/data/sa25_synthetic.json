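{
 "name": "synthetic25",
 "letters": [
  "A",
  "B",
  "C",
  "D",
  "E",
  "F",
  "G",
  "H",
  "I",
  "J",
  "K",
  "L",
  "M",
  "N",
  "O",
  "P",
  "Q",
  "R",
  "S",
  "T",
  "U",
  "V",
  "W",
  "X",
  "Y"
 ],
 "prototypes": {
  "A": [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    0.33186207182973304,
    0.011322500804012101,
    -0.18476841249634707
   ],
   [
    0.6818750353939043,
    -0.11892714979306936,
    -0.11458327264207074
   ],
   [
    0.8985229382591516,
    0.18750049349986742,
    -0.05486907324170152
   ]
  ],
  "B": [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    0.34577098298974396,
    -0.07620696708196517,
    0.13796711742467638
   ],
   [
    0.4197530605553806,
    -0.39013643545347576,
    0.33890228380192583
   ],
   [
    0.08034711257038252,
    -0.41136002955873363,
    0.5084698559543278
   ]
  ],
  "C": [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    0.08720218746730542,
    0.3117202292487196,
    0.19906350036619627
   ],
   [
    0.05159930725799619,
    0.49196185365927525,
    0.5316975211016673
   ],
   [
    -0.07910751969398114,
    0.7997496569239051,
    0.7122034588147504
   ]
  ],
  "D": [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    0.3482449930369097,
    -0.1370325422069812,
    0.0659356292228611
   ],
   [
    0.592274592767577,
    -0.2658503640704033,
    0.32719320944906993
   ],
   [
    0.46954703920309193,
    -0.5812694873232744,
    0.49996104292065824
   ]
  ],
  "E": [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    0.20747770215842654,
    0.2950308725571998,
    0.1196235233772881
   ],
   [
    0.3467236549518661,
    0.6388088228849563,
    0.20225091289852237
   ],
   [
    0.4335971216456304,
    0.6418023559576758,
    0.5721752829315738
   ]
  ],
  "F": [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    -0.10854408269854426,
    -0.1267051504797618,
    0.34141468473548775
   ],
   [
    -0.3677904412072857,
    -0.32132715406317325,
    0.5396912625784989
   ],
   [
    -0.7148077907389057,
    -0.46067619609259947,
    0.6072249845959524
   ]
  ],
  "G": [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    -0.006862724984964891,
    -0.37987051617329254,
    0.007161979336540996
   ],
   [
    -0.22376676096659473,
    -0.6875527575475088,
    0.05897199301940254
   ],
   [
    0.09172736381822352,
    -0.8708100412315241,
    -0.04723641155866203
   ]
  ],
  "H": [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    0.18002169825356648,
    0.31797240475623784,
    0.10433474000272948
   ],
   [
    0.033890427032506026,
    0.6297854858522112,
    -0.056345856301718
   ],
   [
    -0.2871497997618271,
    0.7698836727789722,
    -0.20367430161923805
   ]
  ],
  "I": [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    0.2544805164646063,
    0.26063441407349597,
    0.10820983754018262
   ],
   [
    0.30908037016010537,
    0.49564813782589484,
    0.40178675356809734
   ],
   [
    0.6342635067147462,
    0.6874850866918717,
    0.4448508076071502
   ]
  ],
  "J": [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    0.02835649742319114,
    0.2873577223169334,
    -0.24702519806431236
   ],
   [
    -0.07806656865908514,
    0.02551683710378244,
    0.006969844872436598
   ],
   [
    0.16466848092703257,
    -0.2412559396478665,
    0.12660253809063618
   ]
  ],
  "K": [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    -0.2938645642171749,
    -0.12054510093306622,
    -0.20859649215288062
   ],
   [
    -0.6480967358427893,
    -0.2507754887382504,
    -0.1643289568983328
   ],
   [
    -1.0141329145902325,
    -0.1643152919063771,
    -0.21857054806012938
   ]
  ],
  "L": [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    0.3293482045701236,
    -0.043646422872838174,
    -0.18445798957172174
   ],
   [
    0.6151525720212022,
    -0.26995664275900955,
    -0.29169393466925686
   ],
   [
    0.7968357331654008,
    0.01851235868653056,
    -0.1238342785226291
   ]
  ],
  "M": [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    0.2813217097936193,
    -0.2536931559918415,
    0.029964615827569496
   ],
   [
    0.30239857372938084,
    -0.24735062081281028,
    0.4093266303389544
   ],
   [
    0.16257056001630918,
    0.0803536556137523,
    0.5414554833302678
   ]
  ],
  "N": [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    0.2608270024917568,
    -0.26651367340408877,
    0.07307350176242977
   ],
   [
    0.5605754778650105,
    -0.40882158750837205,
    0.25827422825856916
   ],
   [
    0.8305089829664988,
    -0.6006478648172457,
    0.4446571195266358
   ]
  ],
  "O": [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    0.2520509271945022,
    -0.06570635692374499,
    -0.2766821366843208
   ],
   [
    0.45084590674964964,
    -0.23127963386925834,
    -0.5550093650777944
   ],
   [
    0.1672003140077606,
    -0.08578090465479737,
    -0.7618312631328102
   ]
  ],
  "P": [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    0.11499102475588191,
    -0.34737308483597984,
    -0.10251343403245895
   ],
   [
    0.09471806730852209,
    -0.7265743226249249,
    -0.08853386123249705
   ],
   [
    0.04315004375064899,
    -0.6767404257794273,
    0.2846381120874817
   ]
  ],
  "Q": [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    0.13576311956318673,
    -0.3391534940870256,
    -0.1046101468072468
   ],
   [
    0.15600942219047284,
    -0.5383513986736657,
    0.21836087671996718
   ],
   [
    0.17726989264261886,
    -0.8414701749713148,
    0.4465428213430447
   ]
  ],
  "R": [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    0.23010038130685917,
    0.16950516592596748,
    -0.2504432335816807
   ],
   [
    0.5543302388993031,
    0.3536821789411201,
    -0.17727338103023815
   ],
   [
    0.9070522679261973,
    0.34748696228873965,
    -0.036033197195109806
   ]
  ],
  "S": [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    0.3668106325886519,
    -0.08513796039307965,
    -0.051004779384087914
   ],
   [
    0.4739969314987435,
    0.27525185133632185,
    -0.10605276688229734
   ],
   [
    0.3918798345562596,
    0.29987323093791324,
    -0.476256184014356
   ]
  ],
  "T": [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    0.18595559419860067,
    -0.12429130692906709,
    -0.3072005664189274
   ],
   [
    -0.02873483020900114,
    -0.17401732979029316,
    -0.6167734081187262
   ],
   [
    -0.402380766897047,
    -0.24282649798406014,
    -0.6241227189023779
   ]
  ],
  "U": [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    0.3419154595558246,
    -0.07072810572663693,
    0.14997117582072556
   ],
   [
    0.2606384124697252,
    0.29955266983411577,
    0.1237759688719072
   ],
   [
    -0.08503969804174222,
    0.45680230289715734,
    0.11038952741943307
   ]
  ],
  "V": [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    0.27381178232745157,
    0.1320795442088151,
    -0.22799583737484316
   ],
   [
    0.21620141770528525,
    0.4195416342656697,
    -0.46975313854327916
   ],
   [
    0.47131517317806804,
    0.36460850815725615,
    -0.7459764601953988
   ]
  ],
  "W": [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    0.2501450548407312,
    0.2622133985045942,
    0.1143310333347796
   ],
   [
    -0.09101203086234999,
    0.4287302919061756,
    0.1311823563234024
   ],
   [
    -0.3160940720331764,
    0.7227558171048915,
    0.04581804718900047
   ]
  ],
  "X": [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    0.35602852150375613,
    0.020066033846997747,
    -0.13130516426059022
   ],
   [
    0.22010998189174824,
    -0.24807221119124678,
    -0.36374447276401306
   ],
   [
    0.16217785867855464,
    -0.4459296373440462,
    -0.6829564838416053
   ]
  ],
  "Y": [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    0.27525329557072575,
    0.20733187110892862,
    -0.1601534217552823
   ],
   [
    0.40587184788966235,
    0.3574317605324883,
    -0.4838953204726717
   ],
   [
    0.5460536656381895,
    0.1971470497476082,
    -0.16916071884564043
   ]
  ]
 }
}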