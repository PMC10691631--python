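# fvcsim beam preset (analytic stand-in for a commissioned linac model)
# units: lengths mm, dose cGy, dose rate MU/min
energy_label: 6FFF
sigma_penumbra_mm: 0.8
sigma_lcpe_mm: 1.4
mlc_transmission: 0.012
jaw_transmission: 0.002
leaf_end_offset_mm: 0.3079
leaf_side_offset_mm: 0.1244
dmu_cal_cgy_per_mu: 0.558
max_dose_rate_mu_per_min: 1400
tmr:  # [depth_mm, tissue_maximum_ratio]
  - [0.0, 0.45000000]
  - [1.0, 0.52576531]
  - [2.0, 0.59591837]
  - [3.0, 0.66045918]
  - [4.0, 0.71938776]
  - [5.0, 0.77270408]
  - [6.0, 0.82040816]
  - [7.0, 0.86250000]
  - [8.0, 0.89897959]
  - [9.0, 0.92984694]
  - [10.0, 0.95510204]
  - [11.0, 0.97474490]
  - [12.0, 0.98877551]
  - [13.0, 0.99719388]
  - [14.0, 1.00000000]
  - [15.0, 0.99452255]
  - [16.0, 0.98907509]
  - [17.0, 0.98365748]
  - [18.0, 0.97826954]
  - [19.0, 0.97291112]
  - [20.0, 0.96758204]
  - [21.0, 0.96228215]
  - [22.0, 0.95701130]
  - [23.0, 0.95176931]
  - [24.0, 0.94655604]
  - [25.0, 0.94137132]
  - [26.0, 0.93621501]
  - [27.0, 0.93108693]
  - [28.0, 0.92598695]
  - [29.0, 0.92091489]
  - [30.0, 0.91587063]
  - [31.0, 0.91085399]
  - [32.0, 0.90586483]
  - [33.0, 0.90090299]
  - [34.0, 0.89596834]
  - [35.0, 0.89106071]
  - [36.0, 0.88617997]
  - [37.0, 0.88132596]
  - [38.0, 0.87649854]
  - [39.0, 0.87169756]
  - [40.0, 0.86692287]
  - [41.0, 0.86217434]
  - [42.0, 0.85745182]
  - [43.0, 0.85275517]
  - [44.0, 0.84808424]
  - [45.0, 0.84343890]
  - [46.0, 0.83881900]
  - [47.0, 0.83422441]
  - [48.0, 0.82965499]
  - [49.0, 0.82511059]
  - [50.0, 0.82059108]
  - [51.0, 0.81609633]
  - [52.0, 0.81162620]
  - [53.0, 0.80718056]
  - [54.0, 0.80275926]
  - [55.0, 0.79836219]
  - [56.0, 0.79398920]
  - [57.0, 0.78964016]
  - [58.0, 0.78531494]
  - [59.0, 0.78101341]
  - [60.0, 0.77673545]
  - [61.0, 0.77248091]
  - [62.0, 0.76824969]
  - [63.0, 0.76404163]
  - [64.0, 0.75985663]
  - [65.0, 0.75569455]
  - [66.0, 0.75155527]
  - [67.0, 0.74743866]
  - [68.0, 0.74334460]
  - [69.0, 0.73927296]
  - [70.0, 0.73522363]
  - [71.0, 0.73119648]
  - [72.0, 0.72719138]
  - [73.0, 0.72320822]
  - [74.0, 0.71924688]
  - [75.0, 0.71530724]
  - [76.0, 0.71138918]
  - [77.0, 0.70749258]
  - [78.0, 0.70361732]
  - [79.0, 0.69976329]
  - [80.0, 0.69593037]
  - [81.0, 0.69211844]
  - [82.0, 0.68832739]
  - [83.0, 0.68455711]
  - [84.0, 0.68080748]
  - [85.0, 0.67707839]
  - [86.0, 0.67336973]
  - [87.0, 0.66968137]
  - [88.0, 0.66601323]
  - [89.0, 0.66236517]
  - [90.0, 0.65873709]
  - [91.0, 0.65512889]
  - [92.0, 0.65154045]
  - [93.0, 0.64797167]
  - [94.0, 0.64442244]
  - [95.0, 0.64089264]
  - [96.0, 0.63738218]
  - [97.0, 0.63389095]
  - [98.0, 0.63041884]
  - [99.0, 0.62696575]
  - [100.0, 0.62353158]
  - [101.0, 0.62011621]
  - [102.0, 0.61671955]
  - [103.0, 0.61334150]
  - [104.0, 0.60998195]
  - [105.0, 0.60664080]
  - [106.0, 0.60331795]
  - [107.0, 0.60001331]
  - [108.0, 0.59672676]
  - [109.0, 0.59345822]
  - [110.0, 0.59020758]
  - [111.0, 0.58697475]
  - [112.0, 0.58375962]
  - [113.0, 0.58056210]
  - [114.0, 0.57738210]
  - [115.0, 0.57421952]
  - [116.0, 0.57107425]
  - [117.0, 0.56794622]
  - [118.0, 0.56483532]
  - [119.0, 0.56174146]
  - [120.0, 0.55866455]
  - [121.0, 0.55560449]
  - [122.0, 0.55256119]
  - [123.0, 0.54953456]
  - [124.0, 0.54652451]
  - [125.0, 0.54353095]
  - [126.0, 0.54055379]
  - [127.0, 0.53759293]
  - [128.0, 0.53464829]
  - [129.0, 0.53171978]
  - [130.0, 0.52880730]
  - [131.0, 0.52591079]
  - [132.0, 0.52303014]
  - [133.0, 0.52016526]
  - [134.0, 0.51731608]
  - [135.0, 0.51448251]
  - [136.0, 0.51166445]
  - [137.0, 0.50886183]
  - [138.0, 0.50607457]
  - [139.0, 0.50330257]
  - [140.0, 0.50054575]
  - [141.0, 0.49780403]
  - [142.0, 0.49507733]
  - [143.0, 0.49236557]
  - [144.0, 0.48966866]
  - [145.0, 0.48698652]
  - [146.0, 0.48431908]
  - [147.0, 0.48166624]
  - [148.0, 0.47902794]
  - [149.0, 0.47640408]
  - [150.0, 0.47379460]
  - [151.0, 0.47119941]
  - [152.0, 0.46861844]
  - [153.0, 0.46605161]
  - [154.0, 0.46349883]
  - [155.0, 0.46096004]
  - [156.0, 0.45843515]
  - [157.0, 0.45592409]
  - [158.0, 0.45342679]
  - [159.0, 0.45094316]
  - [160.0, 0.44847314]
  - [161.0, 0.44601665]
  - [162.0, 0.44357362]
  - [163.0, 0.44114396]
  - [164.0, 0.43872762]
  - [165.0, 0.43632451]
  - [166.0, 0.43393456]
  - [167.0, 0.43155770]
  - [168.0, 0.42919387]
  - [169.0, 0.42684298]
  - [170.0, 0.42450496]
  - [171.0, 0.42217976]
  - [172.0, 0.41986729]
  - [173.0, 0.41756748]
  - [174.0, 0.41528028]
  - [175.0, 0.41300560]
  - [176.0, 0.41074338]
  - [177.0, 0.40849355]
  - [178.0, 0.40625605]
  - [179.0, 0.40403080]
  - [180.0, 0.40181774]
  - [181.0, 0.39961680]
  - [182.0, 0.39742792]
  - [183.0, 0.39525102]
  - [184.0, 0.39308605]
  - [185.0, 0.39093294]
  - [186.0, 0.38879163]
  - [187.0, 0.38666204]
  - [188.0, 0.38454411]
  - [189.0, 0.38243779]
  - [190.0, 0.38034301]
  - [191.0, 0.37825970]
  - [192.0, 0.37618780]
  - [193.0, 0.37412724]
  - [194.0, 0.37207798]
  - [195.0, 0.37003994]
  - [196.0, 0.36801306]
  - [197.0, 0.36599729]
  - [198.0, 0.36399255]
  - [199.0, 0.36199880]
  - [200.0, 0.36001597]
of_table:  # [equivalent_square_mm, field_output_factor]
  - [1.000000, 0.22157292]
  - [1.250000, 0.25081632]
  - [1.500000, 0.27896113]
  - [1.750000, 0.30604862]
  - [2.000000, 0.33211850]
  - [2.250000, 0.35720900]
  - [2.500000, 0.38135693]
  - [2.750000, 0.40459768]
  - [3.000000, 0.42696534]
  - [3.250000, 0.44849270]
  - [3.500000, 0.46921134]
  - [3.750000, 0.48915164]
  - [4.000000, 0.50834284]
  - [4.250000, 0.52681307]
  - [4.500000, 0.54458942]
  - [4.750000, 0.56169797]
  - [5.000000, 0.57816380]
  - [5.250000, 0.59401104]
  - [5.429155, 0.60500000]
  - [5.500000, 0.60926295]
  - [5.750000, 0.62394189]
  - [6.000000, 0.63806938]
  - [6.250000, 0.65166614]
  - [6.500000, 0.66475210]
  - [6.750000, 0.67734646]
  - [7.000000, 0.68946768]
  - [7.250000, 0.70113354]
  - [7.500000, 0.71236115]
  - [7.750000, 0.72316696]
  - [8.000000, 0.73356683]
  - [8.250000, 0.74357601]
  - [8.500000, 0.75320917]
  - [8.750000, 0.76248043]
  - [9.000000, 0.77140340]
  - [9.250000, 0.77999116]
  - [9.500000, 0.78825630]
  - [9.750000, 0.79621094]
  - [10.000000, 0.80386674]
  - [10.250000, 0.81123494]
  - [10.500000, 0.81832633]
  - [10.750000, 0.82515132]
  - [11.000000, 0.83171992]
  - [11.250000, 0.83804175]
  - [11.500000, 0.84412608]
  - [11.750000, 0.84998184]
  - [12.000000, 0.85561762]
  - [13.000000, 0.87612157]
  - [14.000000, 0.89371373]
  - [15.000000, 0.90880760]
  - [16.000000, 0.92175797]
  - [17.000000, 0.93286924]
  - [18.000000, 0.94240258]
  - [19.000000, 0.95058207]
  - [20.000000, 0.95759998]
  - [25.000000, 0.98028606]
  - [30.000000, 0.99083398]
  - [40.000000, 0.99801849]
  - [50.000000, 0.99957164]
  - [60.000000, 0.99990740]
  - [80.000000, 0.99999567]
  - [100.000000, 0.99999980]
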