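n,M06-D3,M06L-D3,MN15,PW6B95D3,wB97XD,CCSD(T)/CBS
1,-6.1,-5.8,-6.3,-6.4,-6.4,-6.0
2,-16.6,-15.6,-17.4,-16.2,-16.8,-15.1
3,-30.0,-28.5,-30.7,-29.8,-30.5,-28.0
4,-42.3,-40.4,-42.2,-42.3,-43.8,-39.9
5,-54.9,-52.2,-55.2,-53.6,-55.6,-49.8
6,-68.2,-64.5,-67.8,-65.8,-68.5,-60.9
7,-79.2,-75.5,-79.1,-77.9,-80.9,-72.5
8,-93.2,-88.5,-91.9,-90.0,-94.1,-84.1
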