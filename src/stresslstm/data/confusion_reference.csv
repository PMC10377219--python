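model,tp,fp,fn,tn
NB,712,98,182,242
SVM,894,14,369,8
LSTM,902,20,348,16
DBN,840,46,178,86
BiLSTM,910,88,158,202
E-LSTM,926,76,142,212
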