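region,polygon,phi,psi
proline_favorable,alpha,-110,-75
proline_favorable,alpha,-40,-75
proline_favorable,alpha,-40,10
proline_favorable,alpha,-110,10
proline_favorable,ppii,-110,100
proline_favorable,ppii,-40,100
proline_favorable,ppii,-40,180
proline_favorable,ppii,-110,180
preproline_favorable,beta,-180,60
preproline_favorable,beta,-45,60
preproline_favorable,beta,-45,180
preproline_favorable,beta,-180,180
preproline_favorable,alpha,-90,-60
preproline_favorable,alpha,-45,-60
preproline_favorable,alpha,-45,-10
preproline_favorable,alpha,-90,-10
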