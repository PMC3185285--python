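(((((dsim:0.02120277, dsec:0.02358723):0.02898348, dmel:0.05989652):0.06713426,(dyak:0.09667234, dere:0.08942766):0.03200292):0.43736490, dana:0.60757469):0.11949656,(dpse:0.00957250, dper:0.01847750):0.51906573,(dwil:0.69140554,(dgri:0.39516469,(dmoj:0.38155611, dvir:0.33379389):0.06304531):0.25381446):0.08257927);
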