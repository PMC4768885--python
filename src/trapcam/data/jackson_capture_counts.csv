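date,released,tml_trapped,tml_in_tub,tml_total,tml_ddvp_trapped,tml_ddvp_in_tub,tml_ddvp_total,control_trapped,control_in_tub,control_total
2014-05-23,1636,291,57,348,287,31,318,26,2,28
2014-05-30,903,294,42,336,235,79,314,134,3,137
2014-06-16,1488,401,52,453,381,75,456,13,1,14
2014-06-23,1172,163,4,167,388,69,457,11,1,12
2014-07-07,1217,292,26,318,410,153,563,17,0,17
2014-07-14,1712,244,10,254,543,178,721,47,1,48
2014-07-18,1674,584,52,636,249,56,305,107,6,113
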