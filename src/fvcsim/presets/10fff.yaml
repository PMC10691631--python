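# fvcsim beam preset (analytic stand-in for a commissioned linac model)
# units: lengths mm, dose cGy, dose rate MU/min
energy_label: 10FFF
sigma_penumbra_mm: 0.9
sigma_lcpe_mm: 1.5
mlc_transmission: 0.012
jaw_transmission: 0.002
leaf_end_offset_mm: 0.3754
leaf_side_offset_mm: 0.2034
dmu_cal_cgy_per_mu: 0.547
max_dose_rate_mu_per_min: 2400
tmr:  # [depth_mm, tissue_maximum_ratio]
  - [0.0, 0.45000000]
  - [1.0, 0.49886364]
  - [2.0, 0.54545455]
  - [3.0, 0.58977273]
  - [4.0, 0.63181818]
  - [5.0, 0.67159091]
  - [6.0, 0.70909091]
  - [7.0, 0.74431818]
  - [8.0, 0.77727273]
  - [9.0, 0.80795455]
  - [10.0, 0.83636364]
  - [11.0, 0.86250000]
  - [12.0, 0.88636364]
  - [13.0, 0.90795455]
  - [14.0, 0.92727273]
  - [15.0, 0.94431818]
  - [16.0, 0.95909091]
  - [17.0, 0.97159091]
  - [18.0, 0.98181818]
  - [19.0, 0.98977273]
  - [20.0, 0.99545455]
  - [21.0, 0.99886364]
  - [22.0, 1.00000000]
  - [23.0, 0.99529066]
  - [24.0, 0.99060350]
  - [25.0, 0.98593841]
  - [26.0, 0.98129529]
  - [27.0, 0.97667403]
  - [28.0, 0.97207454]
  - [29.0, 0.96749671]
  - [30.0, 0.96294044]
  - [31.0, 0.95840563]
  - [32.0, 0.95389217]
  - [33.0, 0.94939997]
  - [34.0, 0.94492892]
  - [35.0, 0.94047893]
  - [36.0, 0.93604989]
  - [37.0, 0.93164171]
  - [38.0, 0.92725430]
  - [39.0, 0.92288754]
  - [40.0, 0.91854135]
  - [41.0, 0.91421563]
  - [42.0, 0.90991027]
  - [43.0, 0.90562520]
  - [44.0, 0.90136030]
  - [45.0, 0.89711549]
  - [46.0, 0.89289066]
  - [47.0, 0.88868574]
  - [48.0, 0.88450061]
  - [49.0, 0.88033520]
  - [50.0, 0.87618940]
  - [51.0, 0.87206313]
  - [52.0, 0.86795628]
  - [53.0, 0.86386878]
  - [54.0, 0.85980053]
  - [55.0, 0.85575144]
  - [56.0, 0.85172141]
  - [57.0, 0.84771037]
  - [58.0, 0.84371821]
  - [59.0, 0.83974485]
  - [60.0, 0.83579021]
  - [61.0, 0.83185419]
  - [62.0, 0.82793670]
  - [63.0, 0.82403767]
  - [64.0, 0.82015699]
  - [65.0, 0.81629460]
  - [66.0, 0.81245039]
  - [67.0, 0.80862428]
  - [68.0, 0.80481619]
  - [69.0, 0.80102604]
  - [70.0, 0.79725374]
  - [71.0, 0.79349920]
  - [72.0, 0.78976234]
  - [73.0, 0.78604308]
  - [74.0, 0.78234134]
  - [75.0, 0.77865702]
  - [76.0, 0.77499006]
  - [77.0, 0.77134037]
  - [78.0, 0.76770787]
  - [79.0, 0.76409247]
  - [80.0, 0.76049410]
  - [81.0, 0.75691267]
  - [82.0, 0.75334811]
  - [83.0, 0.74980034]
  - [84.0, 0.74626927]
  - [85.0, 0.74275484]
  - [86.0, 0.73925695]
  - [87.0, 0.73577554]
  - [88.0, 0.73231052]
  - [89.0, 0.72886182]
  - [90.0, 0.72542937]
  - [91.0, 0.72201307]
  - [92.0, 0.71861287]
  - [93.0, 0.71522867]
  - [94.0, 0.71186042]
  - [95.0, 0.70850803]
  - [96.0, 0.70517142]
  - [97.0, 0.70185053]
  - [98.0, 0.69854527]
  - [99.0, 0.69525559]
  - [100.0, 0.69198139]
  - [101.0, 0.68872262]
  - [102.0, 0.68547919]
  - [103.0, 0.68225103]
  - [104.0, 0.67903808]
  - [105.0, 0.67584026]
  - [106.0, 0.67265750]
  - [107.0, 0.66948972]
  - [108.0, 0.66633687]
  - [109.0, 0.66319886]
  - [110.0, 0.66007563]
  - [111.0, 0.65696711]
  - [112.0, 0.65387323]
  - [113.0, 0.65079392]
  - [114.0, 0.64772911]
  - [115.0, 0.64467873]
  - [116.0, 0.64164272]
  - [117.0, 0.63862101]
  - [118.0, 0.63561352]
  - [119.0, 0.63262020]
  - [120.0, 0.62964098]
  - [121.0, 0.62667578]
  - [122.0, 0.62372455]
  - [123.0, 0.62078722]
  - [124.0, 0.61786372]
  - [125.0, 0.61495399]
  - [126.0, 0.61205797]
  - [127.0, 0.60917558]
  - [128.0, 0.60630676]
  - [129.0, 0.60345146]
  - [130.0, 0.60060960]
  - [131.0, 0.59778112]
  - [132.0, 0.59496597]
  - [133.0, 0.59216407]
  - [134.0, 0.58937537]
  - [135.0, 0.58659980]
  - [136.0, 0.58383730]
  - [137.0, 0.58108781]
  - [138.0, 0.57835127]
  - [139.0, 0.57562762]
  - [140.0, 0.57291679]
  - [141.0, 0.57021873]
  - [142.0, 0.56753338]
  - [143.0, 0.56486067]
  - [144.0, 0.56220055]
  - [145.0, 0.55955296]
  - [146.0, 0.55691783]
  - [147.0, 0.55429512]
  - [148.0, 0.55168475]
  - [149.0, 0.54908668]
  - [150.0, 0.54650084]
  - [151.0, 0.54392718]
  - [152.0, 0.54136565]
  - [153.0, 0.53881617]
  - [154.0, 0.53627870]
  - [155.0, 0.53375318]
  - [156.0, 0.53123956]
  - [157.0, 0.52873777]
  - [158.0, 0.52624776]
  - [159.0, 0.52376948]
  - [160.0, 0.52130288]
  - [161.0, 0.51884788]
  - [162.0, 0.51640445]
  - [163.0, 0.51397253]
  - [164.0, 0.51155206]
  - [165.0, 0.50914298]
  - [166.0, 0.50674526]
  - [167.0, 0.50435882]
  - [168.0, 0.50198362]
  - [169.0, 0.49961961]
  - [170.0, 0.49726673]
  - [171.0, 0.49492493]
  - [172.0, 0.49259416]
  - [173.0, 0.49027437]
  - [174.0, 0.48796550]
  - [175.0, 0.48566750]
  - [176.0, 0.48338033]
  - [177.0, 0.48110393]
  - [178.0, 0.47883825]
  - [179.0, 0.47658323]
  - [180.0, 0.47433884]
  - [181.0, 0.47210502]
  - [182.0, 0.46988172]
  - [183.0, 0.46766888]
  - [184.0, 0.46546647]
  - [185.0, 0.46327443]
  - [186.0, 0.46109271]
  - [187.0, 0.45892127]
  - [188.0, 0.45676005]
  - [189.0, 0.45460902]
  - [190.0, 0.45246811]
  - [191.0, 0.45033728]
  - [192.0, 0.44821649]
  - [193.0, 0.44610569]
  - [194.0, 0.44400482]
  - [195.0, 0.44191385]
  - [196.0, 0.43983273]
  - [197.0, 0.43776141]
  - [198.0, 0.43569984]
  - [199.0, 0.43364798]
  - [200.0, 0.43160578]
of_table:  # [equivalent_square_mm, field_output_factor]
  - [1.000000, 0.33434853]
  - [1.250000, 0.34843489]
  - [1.500000, 0.36222316]
  - [1.750000, 0.37571965]
  - [2.000000, 0.38893053]
  - [2.250000, 0.40186184]
  - [2.500000, 0.41451950]
  - [2.750000, 0.42690930]
  - [3.000000, 0.43903691]
  - [3.250000, 0.45090789]
  - [3.500000, 0.46252765]
  - [3.750000, 0.47390151]
  - [4.000000, 0.48503469]
  - [4.250000, 0.49593226]
  - [4.500000, 0.50659923]
  - [4.750000, 0.51704046]
  - [5.000000, 0.52726074]
  - [5.250000, 0.53726474]
  - [5.500000, 0.54705703]
  - [5.576192, 0.55000001]
  - [5.750000, 0.55664211]
  - [6.000000, 0.56602435]
  - [6.250000, 0.57520804]
  - [6.500000, 0.58419739]
  - [6.750000, 0.59299651]
  - [7.000000, 0.60160942]
  - [7.250000, 0.61004007]
  - [7.500000, 0.61829231]
  - [7.750000, 0.62636992]
  - [8.000000, 0.63427659]
  - [8.250000, 0.64201595]
  - [8.500000, 0.64959152]
  - [8.750000, 0.65700679]
  - [9.000000, 0.66426513]
  - [9.250000, 0.67136987]
  - [9.500000, 0.67832427]
  - [9.750000, 0.68513150]
  - [10.000000, 0.69179467]
  - [10.250000, 0.69831684]
  - [10.500000, 0.70470099]
  - [10.750000, 0.71095004]
  - [11.000000, 0.71706685]
  - [11.250000, 0.72305421]
  - [11.500000, 0.72891488]
  - [11.750000, 0.73465152]
  - [12.000000, 0.74026676]
  - [13.000000, 0.76156433]
  - [14.000000, 0.78111554]
  - [15.000000, 0.79906360]
  - [16.000000, 0.81553996]
  - [17.000000, 0.83066528]
  - [18.000000, 0.84455037]
  - [19.000000, 0.85729690]
  - [20.000000, 0.86899825]
  - [25.000000, 0.91459259]
  - [30.000000, 0.94431810]
  - [40.000000, 0.97633258]
  - [50.000000, 0.98994023]
  - [60.000000, 0.99572413]
  - [80.000000, 0.99922750]
  - [100.000000, 0.99986044]
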