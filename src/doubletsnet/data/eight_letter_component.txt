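# Second largest connected component of the 8-letter ladder graph
# (52 words, printed order = node numbering 1..52)
babbling
boggling
bubbling
bumbling
bundling
bungling
burbling
burgling
cackling
cobbling
dabbling
dangling
dumpling
fumbling
gabbling
gambling
gangling
garbling
gargling
giggling
gobbling
goggling
gurgling
hackling
haggling
heckling
hobbling
humbling
jangling
jiggling
jingling
juggling
mangling
mantling
mingling
mumbling
niggling
pickling
rambling
rumbling
rumpling
tackling
tangling
tickling
tingling
tinkling
toggling
tumbling
waggling
warbling
wiggling
wobbling
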