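# shared_in_all	44
# loci	B10	117
# loci	I03	104
# loci	N15	154
# loci	T29	151
# loci	ZH26	159
	B10	I03	N15	T29	ZH26
B10	100.0	64.95726495726495	37.60683760683761	37.60683760683761	37.60683760683761
I03	73.07692307692308	100.0	42.30769230769231	42.30769230769231	42.30769230769231
N15	28.571428571428573	28.571428571428573	100.0	74.67532467532467	52.5974025974026
T29	29.13907284768212	29.13907284768212	76.15894039735099	100.0	53.64238410596027
ZH26	27.67295597484277	27.67295597484277	50.943396226415096	50.943396226415096	100.0
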