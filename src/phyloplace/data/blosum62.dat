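# BLOSUM62 empirical amino-acid model: lower-triangle exchangeabilities then equilibrium frequencies
# residue order: A R N D C Q E G H I L K M F P S T W Y V
0.7357903897
0.4853910555 0.5431618209
 1.45999531 1.199705705 1.170949043
1.955883575 0.716241445 0.6058990037 0.8000165305
1.295201267 1.253758267 0.4929646797 1.173275901 4.325092687
1.729178019 0.4658393677 0.7182066976 2.187774522 1.297446705 0.5009644086
0.2278265742  3.02083361  1.36057419 0.4187633085 1.456141166 0.2320364451 0.6227116697
5.411115141 0.9836929875 0.3716446932 0.4481336617 1.122783104 0.9146659546 0.4263823101 0.7205174412
0.4383883438 3.180100048 0.3973589499 1.839216147 1.240488509 1.355872344 2.414501434 0.2830173263 0.2118881596
1.593137043 0.6484412788 0.3548612492 0.4948870437 2.904101656 1.898173635 0.1914820462 0.538222519 0.312858798 0.2408366148
1.190945703 3.761625208 0.798473249 0.778142664 0.4185557325 0.2181315776 1.032447925 0.222621898 0.2817306942 0.730628273 1.582754142
0.9341875094 0.1453450463 0.261422209 0.2581292894 0.3298015046 0.1407488918 0.4182031923 0.3540581098 0.7748940228 0.8318426401 0.2850788009 0.7676888235
0.4413374712 0.3560084988 1.197188415 1.119831359 0.5276644189 0.4702377337 1.116352479 5.528919178 0.6098463054 2.435341131 0.2362024512 0.5807370932 3.945277675
2.494896077 0.1443569598 0.8585705757 1.934870925 1.277480295 0.7586538086 0.9589897429 0.5307857901 0.4235799922 1.626891057 0.1868480469 0.3726251751 2.802427152 0.5554153975
0.2914090842 0.9265639348 1.769893239 1.071097236 0.4076356489 0.5967193003 0.5242538463 0.539859125 0.1892962924 0.2177211592 0.7520424403 0.4594361736 0.3681664645 0.5040865995 1.509326253
0.6414360114 0.5083589246 0.308055737 0.2533407902 0.2527184479 0.3480722098 1.022507036 0.9843115254 0.7145337039 0.5270073392 1.117029763 0.5854070902 0.3012486008 4.218953969 0.2015559718 3.890963773
0.4061935866 3.364797763 1.517359326 0.3883554092 0.3575444125 1.179091197 0.3419857875 0.6746170932 8.311839405 0.4455702743  6.03055938 2.064839703 0.3745556875 0.3529691845 0.9152598577 0.6914746346 0.8112458563
2.231405689 1.073061184 0.2669247505 1.047383451 1.752165918 1.303875201 0.3322430406 0.7179934869 0.4981384753 1.773855169 0.4541236251 0.9187234157 1.488548054 0.8881010982 0.9516821622 2.575850755 0.2335979096 0.5400276448
0.4882061188 2.074324893 6.747260431 0.8381196102 1.169129578 1.005451683  0.25221483 0.3694053194 0.4969084107 5.151556292 0.3879256221 0.7967515208 0.5619254574 0.5131281269 0.8010102432 2.253074051 4.054419007 0.2665087314           1
      0.074       0.052       0.045       0.054       0.025       0.034       0.054       0.074       0.026       0.068       0.099       0.058       0.025       0.047       0.039       0.057       0.051       0.013       0.032       0.073
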