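raw,canonical
CIPRO,ciprofloxacin
CIPRO XR,ciprofloxacin
CIPROXIN,ciprofloxacin
CILOXAN,ciprofloxacin
CIPROFLOXACIN,ciprofloxacin
LEVAQUIN,levofloxacin
TAVANIC,levofloxacin
QUIXIN,levofloxacin
LEVOFLOXACIN,levofloxacin
AVELOX,moxifloxacin
VIGAMOX,moxifloxacin
MOXEZA,moxifloxacin
MOXIFLOXACIN,moxifloxacin
FLOXIN,ofloxacin
OCUFLOX,ofloxacin
OFLOXACIN,ofloxacin
FACTIVE,gemifloxacin
GEMIFLOXACIN,gemifloxacin
BAXDELA,delafloxacin
DELAFLOXACIN,delafloxacin
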