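name	rule_id	start	end
Helicase ATP-binding domain	PRU00541	51	227
Helicase C-terminal domain	PRU00542	433	602
Dicer double-stranded RNA-binding fold domain	PRU00657	630	722
PAZ	PRU00142	891	1042
RNase III	PRU00177	1276	1403
RNase III	PRU00177	1666	1824
Double-stranded RNA-binding domain	PRU00266	1849	1914
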