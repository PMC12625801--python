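alias,canonical
Palaeopropithecus ingens,Paleopropithecus ingens
Palaeopropithecus maximus,Paleopropithecus maximus
Daubentonia robustus,Daubentonia robusta
Mesopropithecus dolicobrachion,Mesopropithecus dolichobrachion
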