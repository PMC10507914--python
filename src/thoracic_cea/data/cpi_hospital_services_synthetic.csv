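year,index
2013,99.00
2014,99.50
2015,100.00
2016,100.30
2017,100.80
2018,101.40
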